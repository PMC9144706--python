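"""Readers and writers for the delimited-text interfaces.

All files are UTF-8, comma-delimited, decimal-point, with a mandatory header
row.  Documented layouts:

* ``samples.csv`` — sample_id, area, location, compound, cas, concentration_mg_m3
* ``oels.csv`` — substance, cas, tier, oel_15min_mg_m3, source
* ``groups.csv`` — family, class, c_min, c_max, oel_15min_mg_m3, source
* ``iur.csv`` — substance, cas, iur_per_ug_m3
* ``classes.csv`` — substance, cas, clp_class
* ``annotations.csv`` — substance, cas, hydrocarbon_class, carbon_number

The configuration file is YAML with three optional top-level keys:
``scenarios`` (list of {label, et, ef, ed, lt, at_days}), ``criteria``
({hi_max, ir_mixture_max, ir_single_max}) and ``ladder`` (list of dilution
steps).  Absent keys fall back to the package defaults (HI < 1, mixture
IR < 1e-5, single-compound IR < 1e-6, lifetime 70 years, factor-2 ladder
starting at 1:4).
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .oels import Catalogues
from .types import (
    AcceptabilityCriteria,
    CompoundAnnotation,
    CompoundMeasurement,
    ConfigError,
    ExposureScenario,
    FormatError,
    GroupOELRecord,
    IURRecord,
    OELRecord,
    OlfactometerLadder,
    SampleRecord,
    ValidationError,
    normalize_name,
)

PathLike = Union[str, Path]

SAMPLE_COLUMNS = ("sample_id", "area", "location", "compound", "cas", "concentration_mg_m3")


def _read_table(path: PathLike, required: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    # round_trip parsing: written full-precision floats must re-read exactly
    df = pd.read_csv(path, dtype={"cas": "string"}, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{what} file {path} is missing mandatory column(s): {', '.join(missing)}"
        )
    return df


def _clean_cas(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return None
    text = str(value).strip()
    return text or None


def read_sample_table(path: PathLike) -> list[SampleRecord]:
    """Read a per-sample compound concentration table.

    Rows sharing a ``sample_id`` are grouped into one :class:`SampleRecord`
    (compound order preserved).  Concentrations are mg/m^3
    toluene-equivalent.
    """
    df = _read_table(path, SAMPLE_COLUMNS, "sample table")
    records: dict[str, dict] = {}
    for idx, row in df.iterrows():
        try:
            conc = float(row["concentration_mg_m3"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"row {idx}: non-numeric concentration "
                f"{row['concentration_mg_m3']!r} for compound {row['compound']!r}"
            ) from None
        if not math.isfinite(conc) or conc < 0:
            raise ValidationError(
                f"row {idx}: concentration must be finite and >= 0, got {conc!r} "
                f"for compound {row['compound']!r}"
            )
        sid = str(row["sample_id"])
        entry = records.setdefault(
            sid, {"area": str(row["area"]), "location": str(row["location"]), "compounds": []}
        )
        entry["compounds"].append(
            CompoundMeasurement(
                name=str(row["compound"]),
                cas=_clean_cas(row["cas"]),
                concentration=conc,
            )
        )
    return [
        SampleRecord(
            sample_id=sid,
            area=entry["area"],
            location=entry["location"],
            compounds=tuple(entry["compounds"]),
        )
        for sid, entry in records.items()
    ]


def write_sample_table(samples: Sequence[SampleRecord], path: PathLike) -> None:
    """Write sample records in the ``samples.csv`` layout (full precision)."""
    rows = [
        {
            "sample_id": s.sample_id,
            "area": s.area,
            "location": s.location,
            "compound": c.name,
            "cas": c.cas,
            "concentration_mg_m3": repr(c.concentration),
        }
        for s in samples
        for c in s.compounds
    ]
    pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS)).to_csv(path, index=False)


def read_oel_catalogue(path: PathLike) -> list[OELRecord]:
    df = _read_table(path, ("substance", "tier", "oel_15min_mg_m3"), "OEL catalogue")
    records = []
    for idx, row in df.iterrows():
        try:
            oel = float(row["oel_15min_mg_m3"])
        except (TypeError, ValueError):
            raise ValidationError(f"row {idx}: non-numeric OEL") from None
        if oel <= 0:
            raise ValidationError(
                f"row {idx}: OEL must be > 0, got {oel!r} for {row['substance']!r}"
            )
        records.append(
            OELRecord(
                substance=str(row["substance"]),
                cas=_clean_cas(row.get("cas")),
                tier=str(row["tier"]),
                oel_15min=oel,
                source_label=str(row.get("source", "") or ""),
            )
        )
    _check_oel_duplicates(records)
    return records


def _check_oel_duplicates(records: Sequence[OELRecord]) -> None:
    """Reject identical (substance, tier, source) entries with different values.

    Several limits for one substance within a tier from *different* sources
    are legitimate (resolution picks the lowest); the same source stating two
    different numbers is a data error worth failing loudly on.
    """
    seen: dict[tuple, float] = {}
    conflicts = []
    for rec in records:
        key = (rec.cas or normalize_name(rec.substance), rec.tier, rec.source_label)
        if key in seen and seen[key] != rec.oel_15min:
            conflicts.append(f"{rec.substance} / {rec.tier} / {rec.source_label or '-'}")
        seen.setdefault(key, rec.oel_15min)
    if conflicts:
        raise ValidationError(
            "conflicting duplicate OEL entries: " + "; ".join(sorted(set(conflicts)))
        )


def read_group_catalogue(path: PathLike) -> list[GroupOELRecord]:
    df = _read_table(
        path, ("family", "class", "c_min", "c_max", "oel_15min_mg_m3"), "group catalogue"
    )
    return [
        GroupOELRecord(
            family_name=str(row["family"]),
            hydrocarbon_class=str(row["class"]),
            c_min=int(row["c_min"]),
            c_max=int(row["c_max"]),
            oel_15min=float(row["oel_15min_mg_m3"]),
            source_label=str(row.get("source", "") or ""),
        )
        for _, row in df.iterrows()
    ]


def read_iur_catalogue(path: PathLike) -> list[IURRecord]:
    df = _read_table(path, ("substance", "iur_per_ug_m3"), "IUR catalogue")
    return [
        IURRecord(
            substance=str(row["substance"]),
            cas=_clean_cas(row.get("cas")),
            iur=float(row["iur_per_ug_m3"]),
        )
        for _, row in df.iterrows()
    ]


def read_class_map(path: PathLike) -> dict[str, str]:
    """Read the CLP carcinogen classification map (keyed by CAS and name)."""
    df = _read_table(path, ("substance", "clp_class"), "classification map")
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        clp = str(row["clp_class"])
        if clp not in ("1A", "1B", "2", "none"):
            raise ValidationError(
                f"clp_class for {row['substance']!r} must be 1A/1B/2/none, got {clp!r}"
            )
        cas = _clean_cas(row.get("cas"))
        name = "" if pd.isna(row["substance"]) else str(row["substance"]).strip()
        if not cas and not name:
            raise ValidationError("classification row without substance or CAS")
        if cas:
            mapping[cas] = clp
        if name:
            mapping[normalize_name(name)] = clp
    return mapping


def read_annotations(path: PathLike) -> dict[str, CompoundAnnotation]:
    df = _read_table(
        path, ("substance", "hydrocarbon_class", "carbon_number"), "annotation table"
    )
    mapping: dict[str, CompoundAnnotation] = {}
    for _, row in df.iterrows():
        ann = CompoundAnnotation(
            substance=str(row["substance"]),
            cas=_clean_cas(row.get("cas")),
            hydrocarbon_class=str(row["hydrocarbon_class"]),
            carbon_number=int(row["carbon_number"]),
        )
        if ann.cas:
            mapping[ann.cas] = ann
        mapping[normalize_name(ann.substance)] = ann
    return mapping


def read_catalogues(
    oel_path: Optional[PathLike] = None,
    group_path: Optional[PathLike] = None,
    iur_path: Optional[PathLike] = None,
    class_path: Optional[PathLike] = None,
    annotation_path: Optional[PathLike] = None,
) -> Catalogues:
    """Load every catalogue table into one keyed lookup container.

    Any path may be None, yielding an empty catalogue of that kind (an empty
    IUR catalogue simply makes all carcinogenic risks evaluate to zero).
    """
    return Catalogues(
        oels=read_oel_catalogue(oel_path) if oel_path else (),
        groups=read_group_catalogue(group_path) if group_path else (),
        iur=read_iur_catalogue(iur_path) if iur_path else (),
        classes=read_class_map(class_path) if class_path else {},
        annotations=read_annotations(annotation_path) if annotation_path else {},
    )


def write_catalogue_files(catalogues: Catalogues, out_dir: PathLike) -> dict[str, Path]:
    """Write every catalogue of a :class:`Catalogues` container to CSV files.

    Produces oels.csv, groups.csv, iur.csv, classes.csv and annotations.csv
    in the documented layouts; returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["oels"] = out / "oels.csv"
    pd.DataFrame(
        [
            {
                "substance": r.substance,
                "cas": r.cas,
                "tier": r.tier,
                "oel_15min_mg_m3": r.oel_15min,
                "source": r.source_label,
            }
            for r in catalogues.oels
        ],
        columns=["substance", "cas", "tier", "oel_15min_mg_m3", "source"],
    ).to_csv(paths["oels"], index=False)

    paths["groups"] = out / "groups.csv"
    pd.DataFrame(
        [
            {
                "family": g.family_name,
                "class": g.hydrocarbon_class,
                "c_min": g.c_min,
                "c_max": g.c_max,
                "oel_15min_mg_m3": g.oel_15min,
                "source": g.source_label,
            }
            for g in catalogues.groups
        ],
        columns=["family", "class", "c_min", "c_max", "oel_15min_mg_m3", "source"],
    ).to_csv(paths["groups"], index=False)

    paths["iur"] = out / "iur.csv"
    pd.DataFrame(
        [
            {"substance": r.substance, "cas": r.cas, "iur_per_ug_m3": r.iur}
            for r in catalogues.iur
        ],
        columns=["substance", "cas", "iur_per_ug_m3"],
    ).to_csv(paths["iur"], index=False)

    # The classes map is keyed redundantly by CAS and normalised name; emit
    # one row per key (re-reading rebuilds the same mapping).
    paths["classes"] = out / "classes.csv"
    cas_pattern = re.compile(r"^\d{2,7}-\d{2}-\d$")
    class_rows = [
        {
            "substance": "" if cas_pattern.match(key) else key,
            "cas": key if cas_pattern.match(key) else None,
            "clp_class": clp,
        }
        for key, clp in catalogues.classes.items()
    ]
    pd.DataFrame(class_rows, columns=["substance", "cas", "clp_class"]).to_csv(
        paths["classes"], index=False
    )

    paths["annotations"] = out / "annotations.csv"
    ann_seen = set()
    ann_rows = []
    for ann in catalogues.annotations.values():
        if ann.substance in ann_seen:
            continue
        ann_seen.add(ann.substance)
        ann_rows.append(
            {
                "substance": ann.substance,
                "cas": ann.cas,
                "hydrocarbon_class": ann.hydrocarbon_class,
                "carbon_number": ann.carbon_number,
            }
        )
    pd.DataFrame(
        ann_rows, columns=["substance", "cas", "hydrocarbon_class", "carbon_number"]
    ).to_csv(paths["annotations"], index=False)
    return paths


_SCENARIO_REQUIRED = ("et", "ef", "ed")


def load_config(
    path: Optional[PathLike] = None,
) -> tuple[list[ExposureScenario], AcceptabilityCriteria, OlfactometerLadder]:
    """Load exposure scenarios, acceptability criteria and the dilution ladder.

    Absent keys (or ``path=None``) fall back to defaults: no scenarios,
    HI < 1, mixture IR < 1e-5, single IR < 1e-6, lifetime 70 years, and a
    14-step factor-2 ladder starting at 1:4.
    """
    raw = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    scenarios = []
    for entry in raw.get("scenarios", []) or []:
        if not isinstance(entry, dict) or "label" not in entry:
            raise ConfigError("each scenario must be a mapping with a 'label' key")
        label = str(entry["label"])
        for param in _SCENARIO_REQUIRED:
            if param not in entry:
                raise ConfigError(
                    f"scenario {label!r} is missing exposure parameter {param!r}"
                )
        scenarios.append(
            ExposureScenario(
                label=label,
                et=float(entry["et"]),
                ef=float(entry["ef"]),
                ed=float(entry["ed"]),
                lt=float(entry.get("lt", 70.0)),
                at_days=float(entry["at_days"]) if "at_days" in entry else None,
            )
        )

    crit_raw = raw.get("criteria", {}) or {}
    criteria = AcceptabilityCriteria(
        hi_max=float(crit_raw.get("hi_max", 1.0)),
        ir_mixture_max=float(crit_raw.get("ir_mixture_max", 1e-5)),
        ir_single_max=float(crit_raw.get("ir_single_max", 1e-6)),
    )

    ladder_raw = raw.get("ladder")
    ladder = OlfactometerLadder(tuple(float(s) for s in ladder_raw)) if ladder_raw else OlfactometerLadder()
    return scenarios, criteria, ladder
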