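"""Resolution of short-term occupational exposure limits for sample compounds.

A semi-quantified refinery odour sample typically contains tens of VOCs, many
of which have no compound-specific occupational exposure limit (OEL).  Three
assignment methods of increasing coverage are provided:

* **method 1** — compound-specific OELs only, resolved through a four-tier
  source hierarchy (international OELs > national OELs > DNELs > other
  short-term limits), taking the lowest value within a tier as a
  precautionary choice;
* **method 2** — method 1, then a family/group limit (e.g. "Hydrocarbons,
  aliphatic, C6–C8") for each compound the first method left uncovered;
* **method 3** — method 1, then one limit for the whole uncovered
  sub-mixture derived with the reciprocal calculation procedure (RCP): the
  harmonic mean of surrogate group limits weighted by the compounds' mass
  fractions renormalised within that sub-mixture.

Compounds that no method can cover remain *unassigned*; they contribute
nothing to the Hazard Index and are reported through the coverage statistics
(the "N.C.%" of the risk tables), because silently dropping them would
understate the risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .types import (
    CompoundAnnotation,
    CompoundMeasurement,
    GroupOELRecord,
    IURRecord,
    OELRecord,
    OEL_TIERS,
    SampleRecord,
    ValidationError,
    normalize_name,
)

#: Sentinel key under which the RCP pseudo-compound appears in HQ breakdowns.
RCP_PSEUDO_COMPOUND = "rcp_submixture"

logger = logging.getLogger(__name__)


@dataclass
class Catalogues:
    """Keyed lookup structures over all reference-value tables.

    Name keys are normalised (case-insensitive, whitespace-collapsed); CAS
    keys take precedence over names whenever the queried compound carries a
    CAS number that the catalogue knows.
    """

    oels: Sequence[OELRecord] = ()
    groups: Sequence[GroupOELRecord] = ()
    iur: Sequence[IURRecord] = ()
    classes: Mapping[str, str] = field(default_factory=dict)  # key -> CLP class
    annotations: Mapping[str, CompoundAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._oel_by_cas: dict[str, list[OELRecord]] = {}
        self._oel_by_name: dict[str, list[OELRecord]] = {}
        for rec in self.oels:
            if rec.cas:
                self._oel_by_cas.setdefault(rec.cas, []).append(rec)
            self._oel_by_name.setdefault(normalize_name(rec.substance), []).append(rec)
        self._iur_by_cas: dict[str, IURRecord] = {}
        self._iur_by_name: dict[str, IURRecord] = {}
        for rec in self.iur:
            if rec.cas:
                self._iur_by_cas[rec.cas] = rec
            self._iur_by_name[normalize_name(rec.substance)] = rec

    # -- lookups ---------------------------------------------------------

    def oel_candidates(self, compound: CompoundMeasurement) -> list[OELRecord]:
        """All specific-OEL records matching a compound (CAS first, else name)."""
        if compound.cas and compound.cas in self._oel_by_cas:
            return list(self._oel_by_cas[compound.cas])
        return list(self._oel_by_name.get(normalize_name(compound.name), []))

    def iur_for(self, compound: CompoundMeasurement) -> Optional[IURRecord]:
        if compound.cas and compound.cas in self._iur_by_cas:
            return self._iur_by_cas[compound.cas]
        return self._iur_by_name.get(normalize_name(compound.name))

    def clp_class(self, compound: CompoundMeasurement) -> str:
        """Effective CLP class: the measurement's own tag, else the map, else none."""
        if compound.carcinogen_class != "none":
            return compound.carcinogen_class
        if compound.cas and compound.cas in self.classes:
            return self.classes[compound.cas]
        return self.classes.get(normalize_name(compound.name), "none")

    def annotation_for(self, compound: CompoundMeasurement) -> Optional[CompoundAnnotation]:
        if compound.cas and compound.cas in self.annotations:
            return self.annotations[compound.cas]
        return self.annotations.get(normalize_name(compound.name))


@dataclass(frozen=True)
class OELAssignment:
    """The resolved reference value for one compound, with provenance.

    ``method`` is "specific", "group", "rcp" or "unassigned"; ``oel_15min``
    is absent exactly when the method is "unassigned".  ``trace`` is a short
    human-readable account of the decision path for audit logs.
    """

    compound: CompoundMeasurement
    oel_15min: Optional[float]
    method: str
    tier: Optional[str] = None
    trace: str = ""

    def __post_init__(self) -> None:
        if (self.method == "unassigned") != (self.oel_15min is None):
            raise ValidationError(
                "oel_15min must be absent exactly when method='unassigned'"
            )
        if self.oel_15min is not None and self.oel_15min <= 0:
            raise ValidationError("assigned OEL must be > 0")

    @property
    def assigned(self) -> bool:
        return self.oel_15min is not None


@dataclass(frozen=True)
class CoverageSummary:
    """How much of a sample the assignment method managed to cover."""

    n_total: int
    n_assigned: int
    nc_percent_count: float  # % of detected compounds with no assigned OEL
    nc_percent_mass: float   # % of total concentration left unassigned


@dataclass(frozen=True)
class OELAssignmentSet:
    """All assignments for one sample under one method, plus coverage."""

    sample_id: str
    method: int
    assignments: tuple[OELAssignment, ...]
    coverage: CoverageSummary


def resolve_specific_oel(
    compound: CompoundMeasurement, catalogues: Catalogues
) -> OELAssignment:
    """Resolve a compound-specific OEL through the four-tier hierarchy.

    Returns the record from the highest-priority tier containing the
    substance; within a tier with several candidates the lowest value wins
    (precautionary rule).  Absence from every tier is a valid outcome
    (method="unassigned"), not an error.
    """
    candidates = catalogues.oel_candidates(compound)
    for tier in OEL_TIERS:
        in_tier = [r for r in candidates if r.tier == tier]
        if in_tier:
            best = min(in_tier, key=lambda r: r.oel_15min)
            return OELAssignment(
                compound=compound,
                oel_15min=best.oel_15min,
                method="specific",
                tier=tier,
                trace=(
                    f"specific OEL {best.oel_15min} mg/m3 from tier {tier} "
                    f"({best.source_label or 'unlabelled'}); "
                    f"{len(in_tier)} candidate(s) in tier, lowest taken"
                ),
            )
    return OELAssignment(
        compound=compound,
        oel_15min=None,
        method="unassigned",
        trace="no specific OEL in any tier",
    )


def match_group(
    compound: CompoundMeasurement, catalogues: Catalogues
) -> OELAssignment:
    """Assign a family/group limit by structural class and carbon number.

    The compound must be annotated (hydrocarbon class + carbon number) in the
    catalogue metadata; group matching is never inferred from the name.  If
    several groups match, the lowest limit is adopted.
    """
    ann = catalogues.annotation_for(compound)
    if ann is None:
        return OELAssignment(
            compound=compound,
            oel_15min=None,
            method="unassigned",
            trace="no structural annotation; group matching impossible",
        )
    matches = [
        g for g in catalogues.groups if g.contains(ann.hydrocarbon_class, ann.carbon_number)
    ]
    if not matches:
        return OELAssignment(
            compound=compound,
            oel_15min=None,
            method="unassigned",
            trace=(
                f"no group covers {ann.hydrocarbon_class} C{ann.carbon_number}"
            ),
        )
    best = min(matches, key=lambda g: g.oel_15min)
    return OELAssignment(
        compound=compound,
        oel_15min=best.oel_15min,
        method="group",
        trace=(
            f"group OEL {best.oel_15min} mg/m3 from {best.family_name!r} "
            f"({len(matches)} matching group(s), lowest taken)"
        ),
    )


def rcp_oel(
    mass_fractions: Sequence[float], component_oels: Sequence[float]
) -> float:
    """Mixture exposure limit by the reciprocal calculation procedure.

    OEL_mix = 1 / sum_i(f_i / OEL_i): the mass-fraction-weighted harmonic
    mean of the component limits.  The result always lies within
    [min(OELs), max(OELs)] and equals the common value when all limits agree.

    Parameters
    ----------
    mass_fractions
        Positive fractions summing to 1 (tolerance 1e-9).
    component_oels
        Component limits in mg/m^3, all > 0, same length.
    """
    fractions = [float(f) for f in mass_fractions]
    oels = [float(o) for o in component_oels]
    if len(fractions) != len(oels):
        raise ValidationError(
            f"length mismatch: {len(fractions)} fractions vs {len(oels)} OELs"
        )
    if not fractions:
        raise ValidationError("RCP needs at least one component")
    if any(f < 0 for f in fractions):
        raise ValidationError("mass fractions must be non-negative")
    total = sum(fractions)
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"mass fractions must sum to 1, got {total!r}")
    if any(o <= 0 for o in oels):
        raise ValidationError("component OELs must all be > 0")
    return 1.0 / sum(f / o for f, o in zip(fractions, oels))


def assign_oels(
    sample: SampleRecord, catalogues: Catalogues, method: int
) -> OELAssignmentSet:
    """Assign a reference value to every compound of a sample.

    method 1: specific resolution only.
    method 2: method 1, then group fallback for compounds left uncovered.
    method 3: method 1, then a single RCP limit computed over the uncovered
    sub-mixture, with surrogate component limits taken from group matching
    and mass fractions renormalised within the sub-mixture; the sub-mixture
    behaves downstream as one pseudo-compound.

    Compounds no fallback can cover stay unassigned and are counted in the
    coverage summary.  Assignment is independent of compound ordering.
    """
    if method not in (1, 2, 3):
        raise ValidationError(f"method must be 1, 2 or 3, got {method!r}")

    assignments: list[OELAssignment] = [
        resolve_specific_oel(c, catalogues) for c in sample.compounds
    ]

    if method == 2:
        assignments = [
            a if a.assigned else match_group(a.compound, catalogues)
            for a in assignments
        ]
    elif method == 3:
        uncovered_idx = [i for i, a in enumerate(assignments) if not a.assigned]
        surrogates = {
            i: match_group(assignments[i].compound, catalogues)
            for i in uncovered_idx
        }
        # Only compounds with a group surrogate can enter the RCP sub-mixture;
        # zero-concentration compounds carry no mass fraction and stay out.
        rcp_idx = [
            i
            for i in uncovered_idx
            if surrogates[i].assigned and assignments[i].compound.concentration > 0
        ]
        sub_total = sum(assignments[i].compound.concentration for i in rcp_idx)
        if rcp_idx and sub_total > 0:
            fractions = [
                assignments[i].compound.concentration / sub_total for i in rcp_idx
            ]
            limits = [surrogates[i].oel_15min for i in rcp_idx]
            mixture_oel = rcp_oel(fractions, limits)
            for i in rcp_idx:
                assignments[i] = OELAssignment(
                    compound=assignments[i].compound,
                    oel_15min=mixture_oel,
                    method="rcp",
                    trace=(
                        f"RCP sub-mixture limit {mixture_oel:.6g} mg/m3 over "
                        f"{len(rcp_idx)} uncovered compound(s); surrogate from "
                        f"group matching, fractions renormalised"
                    ),
                )

    if logger.isEnabledFor(logging.DEBUG):
        for a in assignments:
            logger.debug(
                "sample %s / %s [method %d]: %s",
                sample.sample_id, a.compound.name, method, a.trace,
            )

    n_total = len(sample.compounds)
    unassigned = [a for a in assignments if not a.assigned]
    total_mass = sample.total_concentration
    unassigned_mass = sum(a.compound.concentration for a in unassigned)
    coverage = CoverageSummary(
        n_total=n_total,
        n_assigned=n_total - len(unassigned),
        nc_percent_count=100.0 * len(unassigned) / n_total if n_total else 0.0,
        nc_percent_mass=100.0 * unassigned_mass / total_mass if total_mass > 0 else 0.0,
    )
    return OELAssignmentSet(
        sample_id=sample.sample_id,
        method=method,
        assignments=tuple(assignments),
        coverage=coverage,
    )
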