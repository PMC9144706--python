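"""Campaign-level assessment driver, summary statistics and reports.

``assess_campaign`` runs the whole pipeline (OEL assignment, Hazard Index,
per-scenario inhalation risk, minimum dilution) over a list of samples and
collects tidy per-sample tables.  ``summarize`` reproduces the summary rows
of a campaign risk table — mean, sample standard deviation (n-1), median,
min, max — at full precision; rendering helpers apply the conventional
display precision (HI to 3 decimals, IR to 3 significant figures, dilution
factors to 2 decimals) only at output time, so machine-readable artefacts
keep every digit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cancer import mixture_inhalation_risk
from .dilution import DilutionRecommendation, dilution_table, minimum_dilution
from .hazard import assess_noncarcinogenic
from .oels import Catalogues
from .types import (
    AcceptabilityCriteria,
    ExposureScenario,
    OlfactometerLadder,
    SampleRecord,
    ValidationError,
)


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    median: float
    min: float
    max: float


@dataclass(frozen=True)
class CampaignSummary:
    """Per-metric summary statistics over an assessed campaign.

    ``sd`` uses the sample (n-1) convention; for a single-sample campaign
    it is reported as 0.0 by documented convention.  The median of an even
    count is the mean of the two central order statistics.
    """

    n_samples: int
    stats: Mapping[str, SummaryStats]


def summarize(
    risk: pd.DataFrame, metrics: Optional[Sequence[str]] = None
) -> CampaignSummary:
    """Summary statistics (full precision) of per-sample risk metrics.

    ``metrics`` defaults to every numeric column of the table.
    """
    if len(risk) == 0:
        raise ValidationError("cannot summarise an empty campaign")
    if metrics is None:
        metrics = [c for c in risk.columns if pd.api.types.is_numeric_dtype(risk[c])]
    stats = {}
    for col in metrics:
        values = np.asarray(risk[col], dtype=float)
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        stats[col] = SummaryStats(
            mean=float(np.mean(values)),
            sd=sd,
            median=float(np.median(values)),
            min=float(np.min(values)),
            max=float(np.max(values)),
        )
    return CampaignSummary(n_samples=len(risk), stats=stats)


@dataclass
class CampaignAssessment:
    """All per-sample results of one campaign under one assignment method."""

    risk: pd.DataFrame               # one row per sample
    hq: pd.DataFrame                 # per-compound HQ breakdown
    recommendations: list[DilutionRecommendation]
    method: int
    scenarios: tuple[ExposureScenario, ...]
    criteria: AcceptabilityCriteria


def assess_campaign(
    samples: Sequence[SampleRecord],
    catalogues: Catalogues,
    scenarios: Sequence[ExposureScenario],
    criteria: AcceptabilityCriteria = AcceptabilityCriteria(),
    method: int = 1,
    ladder: Optional[OlfactometerLadder] = None,
) -> CampaignAssessment:
    """Run the full risk pipeline over a campaign of samples."""
    rows, hq_rows, recs = [], [], []
    for sample in samples:
        nc = assess_noncarcinogenic(sample, catalogues, method)
        carcs = [mixture_inhalation_risk(sample, catalogues, s) for s in scenarios]
        rec = minimum_dilution(nc, carcs, criteria, ladder)
        recs.append(rec)
        row = {
            "sample_id": sample.sample_id,
            "area": sample.area,
            "location": sample.location,
            "method": method,
            "hi": nc.hi,
            "nc_percent_count": nc.nc_percent_count,
            "nc_percent_mass": nc.nc_percent_mass,
        }
        for carc in carcs:
            row[f"ir_{carc.scenario_label}"] = carc.ir_mixture
            row[f"ir_single_max_{carc.scenario_label}"] = carc.ir_single_max
        row["d_min"] = rec.d_min
        rows.append(row)
        for name, hq in nc.hq_by_compound.items():
            hq_rows.append(
                {"sample_id": sample.sample_id, "compound": name, "hq": hq}
            )
    return CampaignAssessment(
        risk=pd.DataFrame(rows),
        hq=pd.DataFrame(hq_rows, columns=["sample_id", "compound", "hq"]),
        recommendations=recs,
        method=method,
        scenarios=tuple(scenarios),
        criteria=criteria,
    )


# -- rendering -----------------------------------------------------------

def format_hi(x: float) -> str:
    return f"{x:.3f}"


def format_ir(x: float) -> str:
    """3 significant figures in scientific notation, e.g. 2.19e-05."""
    return f"{x:.2e}"


def format_dilution(x: float) -> str:
    return f"{x:.2f}"


def _flagged_risk_table(
    risk: pd.DataFrame, criteria: AcceptabilityCriteria
) -> pd.DataFrame:
    """Rendered copy of the risk table with exceedances marked by '*'."""
    out = risk.copy()
    if "hi" in out:
        out["hi"] = [
            format_hi(v) + ("*" if v > criteria.hi_max else "") for v in risk["hi"]
        ]
    for col in risk.columns:
        if col.startswith("ir_") and not col.startswith("ir_single"):
            out[col] = [
                format_ir(v) + ("*" if v > criteria.ir_mixture_max else "")
                for v in risk[col]
            ]
        elif col.startswith("ir_single_max_"):
            out[col] = [
                format_ir(v) + ("*" if v > criteria.ir_single_max else "")
                for v in risk[col]
            ]
    return out


def render_report(
    assessment: CampaignAssessment,
    fmt: str = "text",
    out_dir: Union[str, Path, None] = None,
) -> dict:
    """Emit the campaign report: risk table, dilution table, distribution.

    ``fmt`` is "text" (tables at display precision, exceedances flagged
    with '*') or "json" (full-precision numbers).  When ``out_dir`` is
    given, writes risk, dilution and summary artefacts there and returns
    their paths; otherwise returns the rendered strings/objects.
    """
    if fmt not in ("text", "json"):
        raise ValidationError(f"unknown report format {fmt!r} (use 'text' or 'json')")

    dil_df, dist = dilution_table(assessment.recommendations)
    summary = summarize(
        assessment.risk,
        metrics=[
            c
            for c in assessment.risk.columns
            if c == "hi" or (c.startswith("ir_") and not c.startswith("ir_single"))
            or c.startswith("nc_percent")
        ],
    )

    if fmt == "json":
        payload = {
            "risk": assessment.risk.to_dict(orient="records"),
            "dilution": dil_df.to_dict(orient="records"),
            "distribution": dist,
            "summary": {
                k: vars(v) for k, v in summary.stats.items()
            },
            "n_samples": summary.n_samples,
        }
        if out_dir is None:
            return payload
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "report.json"
        path.write_text(json.dumps(payload, indent=2, default=float), encoding="utf-8")
        return {"report": path}

    risk_text = _flagged_risk_table(assessment.risk, assessment.criteria).to_string(index=False)
    dil_render = dil_df.copy()
    for col in dil_render.columns:
        if col.startswith("d_") and col != "d_min_2dp":
            dil_render[col] = [format_dilution(v) for v in dil_df[col]]
    dil_text = dil_render.to_string(index=False)
    summary_lines = [f"n_samples: {summary.n_samples}"]
    for metric, st in summary.stats.items():
        f = format_hi if metric.startswith(("hi", "nc_")) else format_ir
        summary_lines.append(
            f"{metric}: mean {f(st.mean)} (+/- {f(st.sd)}), "
            f"median {f(st.median)} (min {f(st.min)}; max {f(st.max)})"
        )
    dist_lines = [
        "d_min distribution: "
        f"not necessary {dist['not_necessary']['count']} "
        f"({dist['not_necessary']['percent']:.0f}%), "
        f"(1, 4] {dist['dilution_1_to_4']['count']} "
        f"({dist['dilution_1_to_4']['percent']:.0f}%), "
        f">4 {dist['dilution_above_4']['count']} "
        f"({dist['dilution_above_4']['percent']:.0f}%)"
    ]
    blocks = {
        "risk": risk_text,
        "dilution": dil_text,
        "summary": "\n".join(summary_lines + dist_lines),
    }
    if out_dir is None:
        return blocks
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, text in blocks.items():
        path = out / f"{name}.txt"
        path.write_text(text + "\n", encoding="utf-8")
        paths[name] = path
    return paths
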