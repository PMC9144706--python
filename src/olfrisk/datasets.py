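"""Bundled reference tables and the published example campaign.

The package ships small plain-text fixtures:

* ``groups.csv`` — family/group short-term limits (the method-2 fallback
  catalogue; national group limits, lowest value wins on overlap);
* ``iur.csv`` — inhalation unit risks for the carcinogens relevant to
  refinery emissions (benzene: US EPA IRIS; naphthalene: CalEPA);
* ``classes.csv`` — CLP carcinogen classification map (benzene 1A,
  naphthalene 2; everything else defaults to none);
* ``refinery_campaign.csv`` — per-sample method-1 HI and per-scenario
  mixture IR values published for an 18-sample refinery odour campaign,
  usable to exercise the summary and dilution-policy stages without raw
  concentration data;
* ``default_config.yaml`` — example scenarios/criteria/ladder configuration.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from . import io as _io
from .oels import Catalogues


def _data_path(name: str) -> Path:
    return Path(resources.files("olfrisk.data") / name)


def default_group_catalogue():
    """The bundled family/group OEL records."""
    return _io.read_group_catalogue(_data_path("groups.csv"))


def default_iur_catalogue():
    return _io.read_iur_catalogue(_data_path("iur.csv"))


def default_class_map():
    return _io.read_class_map(_data_path("classes.csv"))


def default_catalogues() -> Catalogues:
    """Catalogues with the bundled groups/IUR/classification tables.

    No compound-specific OELs are bundled (those depend on the user's
    jurisdiction and databases); supply your own ``oels.csv`` or use the
    synthetic generator's catalogues.
    """
    return Catalogues(
        groups=default_group_catalogue(),
        iur=default_iur_catalogue(),
        classes=default_class_map(),
    )


def published_campaign() -> pd.DataFrame:
    """Published per-sample HI and mixture IR values of a refinery campaign.

    Columns: sample_id, area, location, hi (method-1 Hazard Index),
    ir_commercial and ir_institutional (mixture lifetime excess cancer risk
    under the two laboratory scenarios).  Per-compound breakdowns are not
    part of the published record, so single-compound criteria cannot be
    evaluated on this table.
    """
    return pd.read_csv(_data_path("refinery_campaign.csv"))


def default_config_path() -> Path:
    return _data_path("default_config.yaml")
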