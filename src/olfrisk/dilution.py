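"""Minimum-dilution policy for olfactometric presentation.

Because every risk metric here (HI, per-compound IR, mixture IR) is linear
in concentration, diluting a sample by a factor D divides each metric by D.
The smallest dilution restoring acceptability is therefore

    d_min = max(HI / HI_max,
                IR_mix / IR_mix_max   (per scenario),
                max_i IR_i / IR_single_max  (per scenario),
                1)

and the term achieving the maximum is the *binding criterion*.  A sample
already within all criteria needs no dilution (d_min = 1, "not necessary").
The continuous d_min is then snapped upward to the olfactometer's discrete
dilution ladder: the panel must not be presented with any step below that
value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .cancer import CarcRisk
from .hazard import NonCarcRisk
from .types import AcceptabilityCriteria, OlfactometerLadder, ValidationError


class LadderExceededError(ValueError):
    """The required dilution exceeds the olfactometer's top step."""


@dataclass(frozen=True)
class DilutionRecommendation:
    """Minimum dilution for one sample, per criterion and overall.

    ``d_min`` is the maximum of the per-criterion dilutions (all >= 1);
    ``necessary`` is True exactly when d_min > 1; ``ladder_step`` is the
    smallest available olfactometer step >= d_min (None when no dilution is
    needed or no ladder was supplied); ``exceeds_ladder`` flags samples whose
    required dilution is above the instrument's top step, i.e. unanalysable
    at the available dilutions.
    """

    sample_id: str
    d_hi: float
    d_ir_mixture: Mapping[str, float]
    d_ir_single: Mapping[str, float]
    d_min: float
    binding_criterion: str
    necessary: bool
    ladder_step: Optional[float] = None
    exceeds_ladder: bool = False

    @property
    def d_min_2dp(self) -> float:
        """d_min rounded to 2 decimals, the conventional reporting precision."""
        return round(self.d_min, 2)


def minimum_dilution(
    non_carc: Optional[NonCarcRisk],
    carc: Union[CarcRisk, Sequence[CarcRisk], None],
    criteria: AcceptabilityCriteria = AcceptabilityCriteria(),
    ladder: Optional[OlfactometerLadder] = None,
) -> DilutionRecommendation:
    """Derive the minimum dilution from as-sampled (undiluted) risk results.

    ``carc`` may be a single scenario's result or one per scenario.  A
    carcinogenic result whose per-compound breakdown is unavailable
    (``ir_by_compound=None``, e.g. when only published mixture values are
    being re-analysed) skips the single-compound criterion for that
    scenario.  When a ladder is given, d_min is snapped to its smallest
    step >= d_min.
    """
    if isinstance(carc, CarcRisk):
        carc_list: list[CarcRisk] = [carc]
    else:
        carc_list = list(carc) if carc is not None else []

    sample_id = non_carc.sample_id if non_carc is not None else (
        carc_list[0].sample_id if carc_list else ""
    )
    for c in carc_list:
        if non_carc is not None and c.sample_id != non_carc.sample_id:
            raise ValidationError(
                f"risk results mix samples {non_carc.sample_id!r} and {c.sample_id!r}"
            )

    d_hi = max(1.0, non_carc.hi / criteria.hi_max) if non_carc is not None else 1.0
    d_mix = {
        c.scenario_label: max(1.0, c.ir_mixture / criteria.ir_mixture_max)
        for c in carc_list
    }
    d_single = {
        c.scenario_label: (
            max(1.0, c.ir_single_max / criteria.ir_single_max)
            if c.ir_by_compound is not None
            else 1.0
        )
        for c in carc_list
    }

    candidates: list[tuple[float, str]] = [(d_hi, "hi")]
    candidates += [(v, f"ir_mixture[{k}]") for k, v in d_mix.items()]
    candidates += [(v, f"ir_single[{k}]") for k, v in d_single.items()]
    d_min = max(v for v, _ in candidates)
    if d_min <= 1.0:
        binding = "none"
    else:
        binding = next(name for v, name in candidates if v == d_min)

    ladder_step: Optional[float] = None
    exceeds = False
    if ladder is not None and d_min > 1.0:
        try:
            ladder_step = snap_to_ladder(d_min, ladder)
        except LadderExceededError:
            exceeds = True

    return DilutionRecommendation(
        sample_id=sample_id,
        d_hi=d_hi,
        d_ir_mixture=d_mix,
        d_ir_single=d_single,
        d_min=d_min,
        binding_criterion=binding,
        necessary=d_min > 1.0,
        ladder_step=ladder_step,
        exceeds_ladder=exceeds,
    )


def snap_to_ladder(d_min: float, ladder: OlfactometerLadder) -> Optional[float]:
    """Smallest ladder step >= d_min; None when no dilution is needed.

    Raises :class:`LadderExceededError` when d_min exceeds the top step.
    """
    if not math.isfinite(d_min) or d_min < 1.0:
        raise ValidationError(f"d_min must be finite and >= 1, got {d_min!r}")
    if d_min <= 1.0:
        return None
    for step in ladder.steps:
        if step >= d_min:
            return step
    raise LadderExceededError(
        f"required dilution {d_min:.4g} exceeds the ladder top {ladder.top:.4g}; "
        "sample unanalysable at the available dilutions"
    )


def dilution_table(
    recommendations: Sequence[DilutionRecommendation],
) -> tuple[pd.DataFrame, dict]:
    """Tabulate a campaign's dilution recommendations plus a distribution.

    Returns one row per sample (per-criterion dilutions, overall d_min,
    binding criterion, ladder step, necessity) and a summary of how samples
    distribute over d_min = 1 (no dilution needed), 1 < d_min <= 4 (below
    the lowest step of a typical olfactometer) and d_min > 4.
    """
    rows = []
    for rec in recommendations:
        row: dict = {"sample_id": rec.sample_id}
        row["d_hi"] = rec.d_hi
        for label, v in rec.d_ir_mixture.items():
            row[f"d_ir_mixture_{label}"] = v
        for label, v in rec.d_ir_single.items():
            row[f"d_ir_single_{label}"] = v
        row.update(
            d_min=rec.d_min,
            d_min_2dp=rec.d_min_2dp,
            binding=rec.binding_criterion,
            ladder_step=rec.ladder_step,
            necessary=rec.necessary,
            exceeds_ladder=rec.exceeds_ladder,
        )
        rows.append(row)
    df = pd.DataFrame(rows)

    n = len(recommendations)
    n_none = sum(1 for r in recommendations if not r.necessary)
    n_low = sum(1 for r in recommendations if 1.0 < r.d_min <= 4.0)
    n_high = sum(1 for r in recommendations if r.d_min > 4.0)
    dist = {
        "n_samples": n,
        "not_necessary": {"count": n_none, "percent": 100.0 * n_none / n if n else 0.0},
        "dilution_1_to_4": {"count": n_low, "percent": 100.0 * n_low / n if n else 0.0},
        "dilution_above_4": {"count": n_high, "percent": 100.0 * n_high / n if n else 0.0},
    }
    return df, dist
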