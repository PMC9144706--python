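"""Non-carcinogenic risk: Hazard Quotients and the sample Hazard Index.

For every compound with an assigned short-term reference value, the hazard
quotient is HQ = C_exp / OEL (both mg/m^3, so HQ is dimensionless), and the
sample Hazard Index is the dose-addition sum HI = sum_i HQ_i.  HI < 1 is the
acceptability criterion for the as-sampled (undiluted) mixture; dilution is
applied only by the dilution-policy module.

Compounds without an assigned reference value contribute nothing to HI but
are tracked through two coverage statistics: N.C.% by count (share of
detected compounds with no HQ) and by mass (share of total concentration
unassigned) — omitting them silently would understate the risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .oels import Catalogues, OELAssignmentSet, RCP_PSEUDO_COMPOUND, assign_oels
from .types import SampleRecord, ValidationError


@dataclass(frozen=True)
class NonCarcRisk:
    """Hazard Index of one sample under one OEL-assignment method.

    ``hq_by_compound`` maps compound name -> HQ; under method 3 the RCP
    sub-mixture appears as the single pseudo-entry ``rcp_submixture``.
    """

    sample_id: str
    method: int
    hi: float
    hq_by_compound: Mapping[str, float]
    nc_percent_count: float
    nc_percent_mass: float


def hazard_quotient(c_exp: float, oel: float) -> float:
    """HQ = C_exp / OEL (both mg/m^3)."""
    if oel <= 0:
        raise ValidationError(f"OEL must be > 0, got {oel!r}")
    if c_exp < 0:
        raise ValidationError(f"concentration must be >= 0, got {c_exp!r}")
    return c_exp / oel


def hazard_index(sample: SampleRecord, assignments: OELAssignmentSet) -> NonCarcRisk:
    """Sum hazard quotients over the covered compounds of one sample.

    The RCP sub-mixture (method 3) contributes one HQ: its summed
    concentration divided by the shared RCP limit.  Raises if the assignment
    set belongs to a different sample.
    """
    if assignments.sample_id != sample.sample_id:
        raise ValidationError(
            f"assignment set is for sample {assignments.sample_id!r}, "
            f"not {sample.sample_id!r}"
        )
    hq: dict[str, float] = {}
    rcp_mass = 0.0
    rcp_oel_value = None
    for a in assignments.assignments:
        if not a.assigned:
            continue
        if a.method == "rcp":
            rcp_mass += a.compound.concentration
            rcp_oel_value = a.oel_15min  # shared across the sub-mixture
        else:
            hq[a.compound.name] = hq.get(a.compound.name, 0.0) + hazard_quotient(
                a.compound.concentration, a.oel_15min
            )
    if rcp_oel_value is not None:
        hq[RCP_PSEUDO_COMPOUND] = hazard_quotient(rcp_mass, rcp_oel_value)
    return NonCarcRisk(
        sample_id=sample.sample_id,
        method=assignments.method,
        hi=sum(hq.values()),
        hq_by_compound=hq,
        nc_percent_count=assignments.coverage.nc_percent_count,
        nc_percent_mass=assignments.coverage.nc_percent_mass,
    )


def assess_noncarcinogenic(
    sample: SampleRecord, catalogues: Catalogues, method: int
) -> NonCarcRisk:
    """Convenience: assign OELs with the chosen method, then compute HI."""
    return hazard_index(sample, assign_oels(sample, catalogues, method))


def compare_methods(
    sample: SampleRecord, catalogues: Catalogues
) -> tuple[NonCarcRisk, NonCarcRisk, NonCarcRisk]:
    """Hazard Index of one sample under all three assignment methods.

    Because the fallbacks of methods 2 and 3 only add non-negative HQ terms
    for compounds method 1 left out, HI_1 <= HI_2 and HI_1 <= HI_3, and the
    uncovered percentages can only shrink.
    """
    return tuple(assess_noncarcinogenic(sample, catalogues, m) for m in (1, 2, 3))
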