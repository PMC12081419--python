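"""Fiber-burden arithmetic for membrane-filter SEM counting.

The lung-tissue asbestos burden is estimated by ashing a known mass of
freeze-dried tissue, suspending the ash, filtering an aliquot onto a
membrane of known active area, and counting asbestos fibers longer than
1 µm in a number of SEM fields at a calibrated magnification.  Because
only a fraction of the filter is examined, the count is extrapolated to
the whole membrane by simple area proportion:

    C [ff/g dry] = n_f * A / (N_fields * a * p_TS)

where ``n_f`` is the number of countable fibers, ``A`` the active
filtration area, ``a`` the area of one microscope field, and ``p_TS``
the dry tissue mass deposited on the filter.  The counting error is
Poisson: the standard deviation of a count of n is sqrt(n), so the
relative SD of the concentration is 1/sqrt(n_f).

Analytical sensitivity (AS) is the concentration equivalent to a single
counted fiber, ``A / (N_fields * a * p_TS)``; the identity
``C = n_f * AS`` holds exactly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

from scipy import stats

__all__ = [
    "MIL",
    "MineralClass",
    "FilterPrep",
    "FiberRecord",
    "StopReason",
    "CountingSession",
    "AshLoad",
    "ConcentrationResult",
    "InvalidPreparationError",
    "InvalidInputError",
    "InfeasiblePlanError",
    "tissue_mass_on_filter",
    "ash_load",
    "apply_counting_rules",
    "analytical_sensitivity",
    "plan_fields",
    "poisson_interval",
    "compute_concentration",
]

#: fibers per gram in one "mil ff/g dry" reporting unit
MIL = 1.0e6

#: counting rule: only fibers strictly longer than this (µm) are counted
MIN_COUNTED_LENGTH_UM = 1.0

#: advisory ash-load ceiling (mg dry tissue per cm² of filter)
MAX_ASH_LOAD_MG_PER_CM2 = 15.0

#: recommended analytical sensitivity: AS should not exceed 0.1 mil ff/g dry
RECOMMENDED_AS_FF_PER_G = 0.1 * MIL

#: nominal upper end of the reported working range (ff/g dry); a filter
#: with a lower tissue load extends it
WORKING_RANGE_UPPER_FF_PER_G = 300.0 * MIL

WORKING_RANGE_ADVICE = (
    "The working range can be extended by analyzing a filter with a "
    "lower lung-tissue load."
)


class InvalidPreparationError(ValueError):
    """A filter preparation record violates its physical constraints."""


class InvalidInputError(ValueError):
    """A counting session or derived quantity is unusable (e.g. no tissue)."""


class InfeasiblePlanError(ValueError):
    """The requested analytical sensitivity needs more area than the filter has."""


class MineralClass(str, enum.Enum):
    """EDS classification of a counted particle."""

    CHRYSOTILE = "chrysotile"
    AMOSITE = "amosite"
    CROCIDOLITE = "crocidolite"
    ANTHOPHYLLITE = "anthophyllite"
    TREMOLITE = "tremolite"
    ACTINOLITE = "actinolite"
    NON_ASBESTOS = "non_asbestos"

    @property
    def is_asbestos(self) -> bool:
        return self is not MineralClass.NON_ASBESTOS


class StopReason(str, enum.Enum):
    """Why a counting session ended."""

    AREA_TARGET_REACHED = "area_target_reached"
    FIBER_CAP_REACHED = "fiber_cap_reached"


@dataclass(frozen=True)
class FilterPrep:
    """Physical preparation parameters of one membrane filter.

    Parameters
    ----------
    dry_mass_ashed_mg:
        Dry (freeze-dried) tissue mass ashed, mg.
    suspension_volume_ml:
        Volume of water the ash was suspended in, mL.
    filtered_volume_ml:
        Aliquot of the suspension pushed through the membrane, mL.
        Zero is allowed and models a procedural blank.
    active_area_mm2:
        Effective filtration area ``A`` of the membrane, mm².
    field_area_mm2:
        Area ``a`` of one SEM field at the working magnification, mm².
        Calibrated per instrument; never assumed.
    magnification:
        Nominal SEM magnification, dimensionless (informational).
    """

    dry_mass_ashed_mg: float
    suspension_volume_ml: float
    filtered_volume_ml: float
    active_area_mm2: float
    field_area_mm2: float
    magnification: int = 12000

    def __post_init__(self) -> None:
        if self.dry_mass_ashed_mg <= 0:
            raise InvalidPreparationError("dry_mass_ashed_mg must be > 0")
        if self.suspension_volume_ml <= 0:
            raise InvalidPreparationError("suspension_volume_ml must be > 0")
        if self.filtered_volume_ml < 0:
            raise InvalidPreparationError("filtered_volume_ml must be >= 0")
        if self.filtered_volume_ml > self.suspension_volume_ml:
            raise InvalidPreparationError(
                "filtered_volume_ml cannot exceed suspension_volume_ml"
            )
        if self.active_area_mm2 <= 0 or self.field_area_mm2 <= 0:
            raise InvalidPreparationError("areas must be > 0")
        if self.field_area_mm2 >= self.active_area_mm2:
            raise InvalidPreparationError(
                "field_area_mm2 must be smaller than active_area_mm2"
            )
        if self.magnification <= 0:
            raise InvalidPreparationError("magnification must be > 0")


@dataclass(frozen=True)
class FiberRecord:
    """One fiber (or elongated particle) logged on the count sheet."""

    field_index: int
    length_um: float
    width_um: float
    mineral_class: MineralClass

    def __post_init__(self) -> None:
        if self.field_index < 0:
            raise InvalidInputError("field_index must be >= 0")
        if self.length_um <= 0 or self.width_um <= 0:
            raise InvalidInputError("fiber dimensions must be > 0")
        if self.length_um < self.width_um:
            raise InvalidInputError("length_um must be >= width_um")
        object.__setattr__(
            self, "mineral_class", MineralClass(self.mineral_class)
        )

    @property
    def is_countable(self) -> bool:
        """True when the >1 µm asbestos counting rule accepts this record."""
        return (
            self.mineral_class.is_asbestos
            and self.length_um > MIN_COUNTED_LENGTH_UM
        )


@dataclass(frozen=True)
class CountingSession:
    """The examined fields of one filter and every fiber logged in them."""

    n_fields_examined: int
    fibers: tuple[FiberRecord, ...] = field(default_factory=tuple)
    stop_reason: StopReason = StopReason.AREA_TARGET_REACHED

    def __post_init__(self) -> None:
        object.__setattr__(self, "fibers", tuple(self.fibers))
        object.__setattr__(self, "stop_reason", StopReason(self.stop_reason))
        if self.n_fields_examined < 1:
            raise InvalidInputError("n_fields_examined must be >= 1")
        for f in self.fibers:
            if f.field_index >= self.n_fields_examined:
                raise InvalidInputError(
                    f"fiber field_index {f.field_index} outside the "
                    f"{self.n_fields_examined} examined fields"
                )


class AshLoad(NamedTuple):
    """Tissue load on the filter, mg of dry lung per cm²."""

    load_mg_per_cm2: float
    exceeds_limit: bool


@dataclass(frozen=True)
class ConcentrationResult:
    """Concentration estimate with Poisson uncertainty for one session.

    All concentrations are stored in ff/g dry; divide by :data:`MIL`
    for the customary "mil ff/g dry" reporting unit.
    """

    concentration: float
    n_counted: int
    n_fields: int
    poisson_sd: float
    poisson_cv_percent: float
    ci_level: float
    ci_low: float
    ci_high: float
    analytical_sensitivity: float
    tissue_mass_on_filter_g: float
    below_sensitivity: bool
    interval_method: str

    @property
    def concentration_mil(self) -> float:
        return self.concentration / MIL

    @property
    def analytical_sensitivity_mil(self) -> float:
        return self.analytical_sensitivity / MIL

    def to_dict(self, units: str = "mil_ff_per_g") -> dict:
        """Serializable report.  ``units``: ``ff_per_g`` or ``mil_ff_per_g``."""
        if units not in ("ff_per_g", "mil_ff_per_g"):
            raise InvalidInputError(f"unknown units {units!r}")
        scale = MIL if units == "mil_ff_per_g" else 1.0
        return {
            "units": units,
            "concentration": self.concentration / scale,
            "n_counted": self.n_counted,
            "n_fields": self.n_fields,
            "poisson_sd": self.poisson_sd / scale,
            "poisson_cv_percent": self.poisson_cv_percent,
            "ci_level": self.ci_level,
            "ci_low": self.ci_low / scale,
            "ci_high": self.ci_high / scale,
            "analytical_sensitivity": self.analytical_sensitivity / scale,
            "tissue_mass_on_filter_g": self.tissue_mass_on_filter_g,
            "below_sensitivity": self.below_sensitivity,
            "interval_method": self.interval_method,
        }


def tissue_mass_on_filter(prep: FilterPrep) -> float:
    """Dry tissue mass deposited on the filter, in grams (``p_TS``).

    The ash of ``dry_mass_ashed_mg`` is suspended homogeneously, so the
    filtered aliquot carries a proportional share of the tissue:
    100 mg suspended in 100 mL with 20 mL filtered puts 20 mg = 0.020 g
    on the membrane.
    """
    fraction = prep.filtered_volume_ml / prep.suspension_volume_ml
    return prep.dry_mass_ashed_mg * fraction / 1000.0


def ash_load(prep: FilterPrep) -> AshLoad:
    """Tissue load per filter area (mg dry lung / cm²) with overload flag.

    Loads above :data:`MAX_ASH_LOAD_MG_PER_CM2` (15 mg/cm²) risk an
    uncountably dense deposit; the flag is advisory, not an error.
    """
    mass_mg = tissue_mass_on_filter(prep) * 1000.0
    area_cm2 = prep.active_area_mm2 / 100.0
    load = mass_mg / area_cm2
    return AshLoad(load, load > MAX_ASH_LOAD_MG_PER_CM2)


def apply_counting_rules(fibers: Sequence[FiberRecord]) -> int:
    """Number of countable fibers: asbestos class and length > 1 µm.

    Fibers of exactly 1 µm are excluded (the rule is strictly "longer
    than"); non-asbestos particles never count.
    """
    return sum(1 for f in fibers if f.is_countable)


def analytical_sensitivity(prep: FilterPrep, n_fields: int) -> float:
    """Concentration (ff/g dry) equivalent to one counted fiber.

    ``AS = A / (n_fields * a * p_TS)``.  Halves when the examined field
    count doubles; smaller is more sensitive.
    """
    if n_fields < 1:
        raise InvalidInputError("n_fields must be >= 1")
    p_ts = tissue_mass_on_filter(prep)
    if p_ts <= 0:
        raise InvalidInputError(
            "no tissue on the filter (filtered_volume_ml is 0); "
            "analytical sensitivity is undefined"
        )
    return prep.active_area_mm2 / (n_fields * prep.field_area_mm2 * p_ts)


def plan_fields(target_as: float, prep: FilterPrep) -> int:
    """Smallest field count whose analytical sensitivity meets ``target_as``.

    Returns the least integer ``n`` with ``AS(n) <= target_as``.  Raises
    :class:`InfeasiblePlanError` when that would require more fields
    than the filter physically holds (``n * a > A``).
    """
    if target_as <= 0:
        raise InvalidInputError("target_as must be > 0")
    p_ts = tissue_mass_on_filter(prep)
    if p_ts <= 0:
        raise InvalidInputError("no tissue on the filter; cannot plan")
    # start from the continuous solution, then settle the boundary by
    # direct evaluation so float rounding cannot shift the answer
    n = max(1, math.floor(prep.active_area_mm2 / (target_as * prep.field_area_mm2 * p_ts)))
    while analytical_sensitivity(prep, n) > target_as:
        n += 1
    while n > 1 and analytical_sensitivity(prep, n - 1) <= target_as:
        n -= 1
    if n * prep.field_area_mm2 > prep.active_area_mm2:
        raise InfeasiblePlanError(
            f"reaching AS <= {target_as:g} ff/g needs {n} fields covering "
            f"{n * prep.field_area_mm2:g} mm², more than the "
            f"{prep.active_area_mm2:g} mm² active area"
        )
    return n


def poisson_interval(n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) two-sided central confidence interval for a Poisson mean.

    Uses the gamma-quantile form: ``low = qgamma(alpha/2, n)``,
    ``high = qgamma(1 - alpha/2, n + 1)``; for ``n = 0`` the lower bound
    is 0.  Exact intervals are conservative: coverage is at least the
    nominal level for every true mean.
    """
    if not 0 < level < 1:
        raise InvalidInputError("level must be in (0, 1)")
    if n < 0:
        raise InvalidInputError("n must be >= 0")
    alpha = 1.0 - level
    low = 0.0 if n == 0 else float(stats.gamma.ppf(alpha / 2.0, n))
    high = float(stats.gamma.ppf(1.0 - alpha / 2.0, n + 1))
    return low, high


def compute_concentration(
    session: CountingSession,
    prep: FilterPrep,
    ci_level: float = 0.95,
    interval_method: str = "garwood",
) -> ConcentrationResult:
    """Fiber concentration with Poisson uncertainty for one counting session.

    Applies the counting rules to the session's fiber records, then

    ``C = n_f * A / (N_fields * a * p_TS)``   [ff/g dry]

    with ``poisson_sd = C / sqrt(n_f)`` and a confidence interval
    obtained by scaling the count-scale interval by the analytical
    sensitivity.  ``interval_method`` is ``"garwood"`` (exact, default)
    or ``"normal"`` (n ± z·sqrt(n)).

    A zero count is not an error: blanks yield ``concentration = 0``
    with a one-sided exact upper limit and the ``below_sensitivity``
    flag set.
    """
    if interval_method not in ("garwood", "normal"):
        raise InvalidInputError(f"unknown interval method {interval_method!r}")
    if not 0 < ci_level < 1:
        raise InvalidInputError("ci_level must be in (0, 1)")
    p_ts = tissue_mass_on_filter(prep)
    if p_ts <= 0:
        raise InvalidInputError("no tissue on the filter; concentration undefined")
    n_f = apply_counting_rules(session.fibers)
    sens = analytical_sensitivity(prep, session.n_fields_examined)
    conc = n_f * sens
    if n_f > 0:
        sd = conc / math.sqrt(n_f)
        cv = 100.0 / math.sqrt(n_f)
        if interval_method == "garwood":
            lo_counts, hi_counts = poisson_interval(n_f, ci_level)
        else:
            z = float(stats.norm.ppf(0.5 + ci_level / 2.0))
            lo_counts = max(0.0, n_f - z * math.sqrt(n_f))
            hi_counts = n_f + z * math.sqrt(n_f)
    else:
        sd = 0.0
        cv = float("nan")
        # one-sided exact upper bound for a zero count: -ln(1 - level)
        lo_counts = 0.0
        hi_counts = float(stats.gamma.ppf(ci_level, 1))
    return ConcentrationResult(
        concentration=conc,
        n_counted=n_f,
        n_fields=session.n_fields_examined,
        poisson_sd=sd,
        poisson_cv_percent=cv,
        ci_level=ci_level,
        ci_low=lo_counts * sens,
        ci_high=hi_counts * sens,
        analytical_sensitivity=sens,
        tissue_mass_on_filter_g=p_ts,
        below_sensitivity=n_f == 0,
        interval_method=interval_method,
    )
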