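"""Carcinogenic risk: lifetime excess inhalation cancer risk per scenario.

For each carcinogenic or suspected-carcinogenic compound (CLP categories 1A,
1B, 2) the lifetime excess inhalation risk is

    IR = CDI x IUR,    CDI = C_air x (ET x EF x ED) / (AT_hours)

where C_air is the airborne concentration in ug/m^3, ET the exposure time
(hours/day), EF the exposure frequency (days/year), ED the exposure duration
(years), and AT the averaging time — for carcinogens the whole lifetime
(LT = 70 years by convention), i.e. AT_hours = LT x 365 x 24.  The IUR
(inhalation unit risk) is the excess lifetime cancer risk per unit
concentration, per (ug/m^3).

The scenario-dependent part collapses into one dimensionless multiplier
m = (ET/24)(EF/365)(ED x 365 / AT_days), so that IR = C_air[ug/m^3] x m x IUR
and, for any two scenarios, all per-compound and mixture IRs differ by the
same constant ratio m1/m2.  Per-compound risks are summed over the
carcinogenic fraction of the sample to give the mixture risk.

Concentrations enter this module in mg/m^3 (the package-wide unit) and are
converted to ug/m^3 (x1000) here, because published IURs are per (ug/m^3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .oels import Catalogues
from .types import ExposureScenario, SampleRecord, ValidationError

logger = logging.getLogger(__name__)

#: mg/m^3 -> ug/m^3
MG_TO_UG = 1000.0

#: CLP categories entering the carcinogenic assessment.
CARCINOGENIC_CLP = ("1A", "1B", "2")

#: Example laboratory workloads.  The absolute parameters are placeholders —
#: every laboratory must supply its own panel workload — but their
#: CDI-multiplier ratio (~5.52) reproduces the commercial/institutional risk
#: ratio observed in published refinery-campaign assessments.
DEFAULT_SCENARIOS = (
    ExposureScenario(label="commercial", et=3.0, ef=221.0, ed=25.0, lt=70.0),
    ExposureScenario(label="institutional", et=2.0, ef=60.0, ed=25.0, lt=70.0),
)


@dataclass(frozen=True)
class CarcRisk:
    """Carcinogenic risk of one sample under one exposure scenario.

    ``ir_by_compound`` contains only compounds with CLP class 1A/1B/2;
    carcinogens lacking an IUR appear in ``gaps`` and contribute zero.
    ``ir_by_compound`` is None when only the mixture total is known (e.g.
    when re-analysing published campaign tables that print no per-compound
    breakdown); downstream consumers then skip per-compound criteria.
    """

    sample_id: str
    scenario_label: str
    ir_mixture: float
    ir_by_compound: Optional[Mapping[str, float]]
    cdi_multiplier: float
    gaps: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ir_single_max(self) -> float:
        """Largest per-compound risk (0 when no carcinogen is present)."""
        if self.ir_by_compound is None:
            return 0.0
        return max(self.ir_by_compound.values(), default=0.0)

    @classmethod
    def from_mixture_value(
        cls, sample_id: str, scenario_label: str, ir_mixture: float
    ) -> "CarcRisk":
        """Wrap a known mixture risk with no per-compound breakdown."""
        return cls(
            sample_id=sample_id,
            scenario_label=scenario_label,
            ir_mixture=float(ir_mixture),
            ir_by_compound=None,
            cdi_multiplier=float("nan"),
        )


def cdi_multiplier(scenario: ExposureScenario) -> float:
    """Dimensionless factor m with CDI(ug/m^3) = C_air(ug/m^3) x m.

    m = (ET/24) x (EF/365) x (ED x 365 / AT_days).  With lifetime averaging
    (AT_days = LT x 365) this reduces to (ET/24)(EF/365)(ED/LT); continuous
    lifetime exposure (ET=24, EF=365, ED=LT) gives exactly 1.
    """
    m = (
        (scenario.et / 24.0)
        * (scenario.ef / 365.0)
        * (scenario.ed * 365.0 / scenario.averaging_days)
    )
    logger.debug(
        "scenario %s: m = (ET/24)(EF/365)(ED*365/AT_days) = "
        "(%g/24)(%g/365)(%g*365/%g) = %.6g",
        scenario.label, scenario.et, scenario.ef, scenario.ed,
        scenario.averaging_days, m,
    )
    return m


def inhalation_risk_compound(
    c_air: float, iur: float, scenario: ExposureScenario
) -> float:
    """Lifetime excess risk of one compound: (C_air x 1000) x m x IUR.

    ``c_air`` in mg/m^3, ``iur`` per (ug/m^3).
    """
    if c_air < 0:
        raise ValidationError(f"concentration must be >= 0, got {c_air!r}")
    if iur < 0:
        raise ValidationError(f"IUR must be >= 0, got {iur!r}")
    return c_air * MG_TO_UG * cdi_multiplier(scenario) * iur


def mixture_inhalation_risk(
    sample: SampleRecord,
    catalogues: Catalogues,
    scenario: ExposureScenario,
) -> CarcRisk:
    """Total lifetime excess risk of a sample's carcinogenic fraction.

    Filters the sample to CLP classes 1A/1B/2 (using the measurement's own
    tag or the catalogue classification map), computes per-compound risks
    and sums them.  Carcinogens without an IUR are reported in ``gaps`` and
    contribute zero — a reported gap, not a silent omission.
    """
    m = cdi_multiplier(scenario)
    ir: dict[str, float] = {}
    gaps: list[str] = []
    for compound in sample.compounds:
        if catalogues.clp_class(compound) not in CARCINOGENIC_CLP:
            continue
        rec = catalogues.iur_for(compound)
        if rec is None or rec.iur == 0:
            gaps.append(compound.name)
            continue
        ir[compound.name] = ir.get(compound.name, 0.0) + inhalation_risk_compound(
            compound.concentration, rec.iur, scenario
        )
    return CarcRisk(
        sample_id=sample.sample_id,
        scenario_label=scenario.label,
        ir_mixture=sum(ir.values()),
        ir_by_compound=ir,
        cdi_multiplier=m,
        gaps=tuple(gaps),
    )


def assess_carcinogenic(
    sample: SampleRecord,
    catalogues: Catalogues,
    scenarios: Sequence[ExposureScenario],
) -> list[CarcRisk]:
    """Mixture inhalation risk of one sample under every scenario."""
    if not scenarios:
        raise ValidationError("at least one exposure scenario is required")
    return [mixture_inhalation_risk(sample, catalogues, s) for s in scenarios]
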