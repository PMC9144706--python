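"""Domain types for panellist risk assessment in dynamic olfactometry.

Dynamic olfactometry (EN 13725) determines the odour concentration of a
sample by presenting it to human assessors ("panellists") at decreasing
dilutions.  Because the assessors sniff the raw, source-collected emission
sample, they are occupationally exposed to whatever hazardous volatiles the
sample contains.  The types below carry the data this package needs to
quantify that exposure: per-sample compound concentration tables
(mg/m^3 toluene-equivalent, as produced by TD-GC-MS semi-quantification),
catalogues of short-term (15-min) occupational exposure limits, inhalation
unit risks and carcinogen classifications, and the exposure-scenario and
acceptability parameters of a given olfactometric laboratory.

All concentrations and exposure limits are held internally in mg/m^3; the
conversion to ug/m^3 required by inhalation-unit-risk arithmetic happens
only inside the carcinogenic-risk module.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence


class ValidationError(ValueError):
    """Raised when an input value violates a domain invariant."""


class FormatError(ValueError):
    """Raised when an input file does not have the documented layout."""


class ConfigError(ValueError):
    """Raised when a configuration file is incomplete or inconsistent."""


#: CLP carcinogen categories (Regulation EC 1272/2008): 1A known, 1B presumed,
#: 2 suspected.  "none" means not classified as carcinogenic.
CARCINOGEN_CLASSES = ("1A", "1B", "2", "none")

#: Hierarchy of sources for a compound-specific short-term OEL, highest
#: priority first.
OEL_TIERS = ("international_oel", "national_oel", "dnel", "other_short_term")

#: Structural classes used for group/family exposure limits.
HYDROCARBON_CLASSES = ("aliphatic", "aromatic", "petroleum_fraction")


def normalize_name(name: str) -> str:
    """Normalise a substance name for lookup: casefold, collapse whitespace."""
    return re.sub(r"\s+", " ", name.strip()).casefold()


def _require_finite_nonneg(value: float, what: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValidationError(f"{what} must be finite and >= 0, got {value!r}")
    return value


def _require_positive(value: float, what: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{what} must be finite and > 0, got {value!r}")
    return value


@dataclass(frozen=True)
class CompoundMeasurement:
    """One semi-quantified compound in an odour sample.

    Parameters
    ----------
    name
        Substance name as reported by the GC-MS library search.
    cas
        Optional CAS registry number (used preferentially for catalogue
        lookups when present).
    concentration
        Concentration in mg/m^3 toluene-equivalent; must be finite and >= 0.
    carcinogen_class
        CLP category: "1A", "1B", "2" or "none".
    """

    name: str
    concentration: float
    cas: Optional[str] = None
    carcinogen_class: str = "none"

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValidationError("compound name must be non-empty")
        _require_finite_nonneg(self.concentration, f"concentration of {self.name!r}")
        if self.carcinogen_class not in CARCINOGEN_CLASSES:
            raise ValidationError(
                f"carcinogen_class of {self.name!r} must be one of "
                f"{CARCINOGEN_CLASSES}, got {self.carcinogen_class!r}"
            )

    @property
    def key(self) -> str:
        """Lookup key: CAS when available, else normalised name."""
        return self.cas if self.cas else normalize_name(self.name)


@dataclass(frozen=True)
class SampleRecord:
    """One odour sample: source metadata plus its compound measurements."""

    sample_id: str
    area: str
    location: str
    compounds: tuple[CompoundMeasurement, ...]

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        object.__setattr__(self, "compounds", tuple(self.compounds))

    @property
    def total_concentration(self) -> float:
        """Summed concentration over all compounds (mg/m^3)."""
        return sum(c.concentration for c in self.compounds)

    def scaled(self, factor: float) -> "SampleRecord":
        """Return a copy with every concentration multiplied by ``factor``.

        Dividing by a dilution factor D is ``scaled(1 / D)``.
        """
        factor = _require_finite_nonneg(factor, "scale factor")
        return SampleRecord(
            sample_id=self.sample_id,
            area=self.area,
            location=self.location,
            compounds=tuple(
                CompoundMeasurement(
                    name=c.name,
                    cas=c.cas,
                    concentration=c.concentration * factor,
                    carcinogen_class=c.carcinogen_class,
                )
                for c in self.compounds
            ),
        )


@dataclass(frozen=True)
class OELRecord:
    """A compound-specific short-term (15-min) occupational exposure limit."""

    substance: str
    oel_15min: float  # mg/m^3
    tier: str
    cas: Optional[str] = None
    source_label: str = ""

    def __post_init__(self) -> None:
        _require_positive(self.oel_15min, f"OEL of {self.substance!r}")
        if self.tier not in OEL_TIERS:
            raise ValidationError(
                f"tier of {self.substance!r} must be one of {OEL_TIERS}, "
                f"got {self.tier!r}"
            )


@dataclass(frozen=True)
class GroupOELRecord:
    """A short-term exposure limit for a family/group of chemicals.

    Group limits (e.g. "Hydrocarbons, aliphatic, C6-C8") describe an entire
    structural class over a carbon-number range and serve as fallbacks for
    compounds lacking a specific OEL.
    """

    family_name: str
    hydrocarbon_class: str
    c_min: int
    c_max: int
    oel_15min: float  # mg/m^3
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.hydrocarbon_class not in HYDROCARBON_CLASSES:
            raise ValidationError(
                f"hydrocarbon_class of {self.family_name!r} must be one of "
                f"{HYDROCARBON_CLASSES}, got {self.hydrocarbon_class!r}"
            )
        if self.c_min > self.c_max:
            raise ValidationError(
                f"carbon range of {self.family_name!r} inverted: "
                f"C{self.c_min} > C{self.c_max}"
            )
        _require_positive(self.oel_15min, f"group OEL of {self.family_name!r}")

    def contains(self, hydrocarbon_class: str, carbon_number: int) -> bool:
        return (
            hydrocarbon_class == self.hydrocarbon_class
            and self.c_min <= carbon_number <= self.c_max
        )


@dataclass(frozen=True)
class IURRecord:
    """An inhalation unit risk: excess lifetime cancer risk per (ug/m^3)."""

    substance: str
    iur: float
    cas: Optional[str] = None

    def __post_init__(self) -> None:
        _require_finite_nonneg(self.iur, f"IUR of {self.substance!r}")


@dataclass(frozen=True)
class CompoundAnnotation:
    """Structural metadata enabling group/RCP matching for one substance."""

    substance: str
    hydrocarbon_class: str  # aliphatic | aromatic | petroleum_fraction | other
    carbon_number: int
    cas: Optional[str] = None


@dataclass(frozen=True)
class ExposureScenario:
    """Exposure parameters of one olfactometric laboratory's panel workload.

    The chronic-daily-intake multiplier derived from these parameters scales
    the as-sampled airborne concentration to a lifetime-averaged exposure
    concentration (see :func:`olfrisk.cancer.cdi_multiplier`).

    Parameters
    ----------
    label : str
        Scenario name, e.g. "commercial" or "institutional".
    et : float
        Exposure time, hours/day; 0 < et <= 24.
    ef : float
        Exposure frequency, days/year; 0 < ef <= 365.
    ed : float
        Exposure duration, years.
    lt : float
        Lifetime over which a carcinogenic dose is averaged, years (70 by
        convention).
    at_days : float, optional
        Averaging time in days.  Defaults to lt * 365 (lifetime averaging,
        the convention for carcinogens).
    """

    label: str
    et: float
    ef: float
    ed: float
    lt: float = 70.0
    at_days: Optional[float] = None

    def __post_init__(self) -> None:
        for attr in ("et", "ef", "ed", "lt"):
            _require_positive(getattr(self, attr), f"{attr} of scenario {self.label!r}")
        if not 0 < self.et <= 24:
            raise ValidationError(
                f"et of scenario {self.label!r} must be in (0, 24] hours/day"
            )
        if not 0 < self.ef <= 365:
            raise ValidationError(
                f"ef of scenario {self.label!r} must be in (0, 365] days/year"
            )
        if self.at_days is not None:
            _require_positive(self.at_days, f"at_days of scenario {self.label!r}")

    @property
    def averaging_days(self) -> float:
        """Averaging time in days (defaults to lifetime: lt * 365)."""
        return self.at_days if self.at_days is not None else self.lt * 365.0


@dataclass(frozen=True)
class AcceptabilityCriteria:
    """Risk-acceptability thresholds for panellist exposure.

    Defaults: HI < 1 (non-carcinogenic); lifetime excess cancer risk below
    1e-6 for a single compound and 1e-5 for the mixture.
    """

    hi_max: float = 1.0
    ir_mixture_max: float = 1e-5
    ir_single_max: float = 1e-6

    def __post_init__(self) -> None:
        _require_positive(self.hi_max, "hi_max")
        _require_positive(self.ir_mixture_max, "ir_mixture_max")
        _require_positive(self.ir_single_max, "ir_single_max")
        if self.ir_single_max > self.ir_mixture_max:
            raise ValidationError(
                "ir_single_max must not exceed ir_mixture_max "
                f"({self.ir_single_max} > {self.ir_mixture_max})"
            )


def default_ladder_steps(first: float = 4.0, ratio: float = 2.0, n: int = 14) -> tuple[float, ...]:
    """Geometric dilution-step series, e.g. 4, 8, 16, ... (14 steps by default)."""
    return tuple(first * ratio**k for k in range(n))


@dataclass(frozen=True)
class OlfactometerLadder:
    """The discrete dilution steps an olfactometer can present.

    Commercial instruments typically offer ~14 steps starting at 1:4.
    """

    steps: tuple[float, ...] = field(default_factory=default_ladder_steps)

    def __post_init__(self) -> None:
        steps = tuple(float(s) for s in self.steps)
        if not steps:
            raise ValidationError("ladder must have at least one step")
        if any(s <= 1 for s in steps):
            raise ValidationError("all ladder steps must be > 1")
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValidationError("ladder steps must be strictly increasing")
        object.__setattr__(self, "steps", steps)

    @property
    def top(self) -> float:
        return self.steps[-1]


def as_sample_tuple(compounds: Sequence[CompoundMeasurement]) -> tuple[CompoundMeasurement, ...]:
    return tuple(compounds)
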