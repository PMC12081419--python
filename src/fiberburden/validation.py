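"""Precision and trueness verification against certified reference materials.

The counting method is verified by measuring homogenized lung-tissue
CRMs (BCR-665, amosite + crocidolite; BCR-666, anthophyllite) eight
times and checking, in the style of ISO conformity assessment:

* **Precision** — the within-laboratory SD ``s_w`` of the replicates is
  compared to a specified reference SD ``sigma_w0`` (here the Poisson
  counting SD) through ``chi2_c = (s_w / sigma_w0)**2``, which under the
  null is distributed as chi²(n-1)/(n-1); the test passes when
  ``chi2_c < quantile(chi², n-1, 0.95) / (n-1)``.
* **Trueness** — the absolute difference between the replicate mean and
  the certified value must not exceed ``k * sqrt(u_meas² + u_crm²)``,
  the expanded uncertainty of the comparison (coverage factor k = 2).

The CRM certificate states an expanded uncertainty ``U``; the standard
uncertainty is recovered as ``u = U / t`` with the certificate's
t-factor (2.45 for these materials, a two-sided 95% Student factor).

``sigma_w0`` and ``u_meas`` are deliberately *supplied* inputs, not
derived: the reference SD depends on how many fibers the laboratory
counts per measurement, and the standard uncertainty of the result
carries laboratory-specific components beyond the replicate scatter.
The helper :func:`poisson_reference_sd` gives the pure-Poisson choice
``C / sqrt(n_max)`` but is never invoked implicitly.

All quantities in this module are in "mil ff/g dry" (10⁶ fibers per
gram of dry tissue) unless noted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CRMSpec",
    "ReplicateSet",
    "ValidationResult",
    "ConfigurationError",
    "u_from_expanded",
    "precision_statistic",
    "chi2_threshold",
    "trueness_bound",
    "poisson_reference_sd",
    "summarize_replicates",
    "validate_against_crm",
    "load_crm",
    "bundled_crm_names",
]

DEFAULT_T_FACTOR = 2.45
DEFAULT_COVERAGE_K = 2.0


class ConfigurationError(ValueError):
    """A required supplied value (sigma_w0, u_meas, ...) is missing or invalid."""


@dataclass(frozen=True)
class CRMSpec:
    """A certified reference material's certificate values.

    ``certified_value`` and ``expanded_uncertainty`` in mil ff/g dry;
    ``t_factor`` converts the expanded uncertainty back to a standard
    uncertainty (u = U / t).
    """

    name: str
    certified_value: float
    expanded_uncertainty: float
    t_factor: float = DEFAULT_T_FACTOR
    analyte: str = ""

    def __post_init__(self) -> None:
        if self.certified_value <= 0:
            raise ConfigurationError("certified_value must be > 0")
        if self.expanded_uncertainty <= 0:
            raise ConfigurationError("expanded_uncertainty must be > 0")
        if self.t_factor <= 1:
            raise ConfigurationError("t_factor must be > 1")

    @property
    def standard_uncertainty(self) -> float:
        return u_from_expanded(self.expanded_uncertainty, self.t_factor)


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate measurements of one CRM, as raw values or (mean, sd, n).

    When raw ``measurements`` are given, ``mean`` and ``sd`` are the
    arithmetic mean and the n-1 sample SD.  Published tables often give
    only the summary, so a summary-only set (empty measurements) is
    accepted too.
    """

    mean: float
    sd: float
    n: int
    measurements: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        if self.n < 2:
            raise ConfigurationError("need at least 2 replicates")
        if self.sd < 0:
            raise ConfigurationError("sd must be >= 0")
        if self.measurements and len(self.measurements) != self.n:
            raise ConfigurationError("n does not match number of measurements")


@dataclass(frozen=True)
class ValidationResult:
    """Every statistic and verdict of one CRM precision/trueness check."""

    crm_name: str
    n: int
    mean: float
    sd: float
    certified_value: float
    sigma_w0: float
    u_meas: float
    u_bcr: float
    chi2_c: float
    chi2_threshold: float
    precision_pass: bool
    abs_diff: float
    trueness_bound: float
    k: float
    level: float
    trueness_pass: bool

    def to_dict(self) -> dict:
        return {
            "crm_name": self.crm_name,
            "units": "mil_ff_per_g",
            "n_replicates": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "certified_value": self.certified_value,
            "sigma_w0": self.sigma_w0,
            "u_meas": self.u_meas,
            "u_bcr": self.u_bcr,
            "chi2_c": self.chi2_c,
            "chi2_threshold": self.chi2_threshold,
            "precision_pass": self.precision_pass,
            "abs_diff": self.abs_diff,
            "trueness_bound": self.trueness_bound,
            "coverage_k": self.k,
            "level": self.level,
            "trueness_pass": self.trueness_pass,
        }


def u_from_expanded(U: float, t_factor: float) -> float:
    """Standard uncertainty from a certificate's expanded uncertainty: U / t."""
    if U <= 0 or t_factor <= 0:
        raise ConfigurationError("U and t_factor must be > 0")
    return U / t_factor


def precision_statistic(s_w: float, sigma_w0: float) -> float:
    """Repeatability test statistic ``(s_w / sigma_w0)**2``."""
    if sigma_w0 <= 0:
        raise ConfigurationError("sigma_w0 must be > 0")
    if s_w < 0:
        raise ConfigurationError("s_w must be >= 0")
    return (s_w / sigma_w0) ** 2


def chi2_threshold(n: int, level: float = 0.95) -> float:
    """Critical value ``quantile(chi², df=n-1, level) / (n-1)``.

    Strictly decreasing in n and tending to 1: with more replicates a
    smaller excess over the reference SD is already significant.
    """
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    if not 0 < level < 1:
        raise ConfigurationError("level must be in (0, 1)")
    df = n - 1
    return float(stats.chi2.ppf(level, df)) / df


def trueness_bound(k: float, u_meas: float, u_bcr: float) -> float:
    """Acceptance bound for the bias check: ``k * sqrt(u_meas² + u_bcr²)``."""
    if k <= 0:
        raise ConfigurationError("k must be > 0")
    if u_meas < 0 or u_bcr < 0:
        raise ConfigurationError("uncertainties must be >= 0")
    return k * math.hypot(u_meas, u_bcr)


def poisson_reference_sd(concentration: float, n_max: int = 50) -> float:
    """Poisson reference SD ``C / sqrt(n_max)`` for a count capped at n_max.

    Convenience only — pass the result to :func:`validate_against_crm`
    explicitly if this is the reference you want.
    """
    if concentration < 0 or n_max < 1:
        raise ConfigurationError("need concentration >= 0 and n_max >= 1")
    return concentration / math.sqrt(n_max)


def summarize_replicates(values: Sequence[float]) -> ReplicateSet:
    """Arithmetic mean and n-1 sample SD of raw replicate values."""
    vals = tuple(float(v) for v in values)
    if len(vals) < 2:
        raise ConfigurationError("need at least 2 replicate values")
    arr = np.asarray(vals)
    return ReplicateSet(
        mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=len(vals),
        measurements=vals,
    )


def validate_against_crm(
    reps: ReplicateSet,
    crm: CRMSpec,
    sigma_w0: float,
    u_meas: float,
    k: float = DEFAULT_COVERAGE_K,
    level: float = 0.95,
) -> ValidationResult:
    """Run the precision and trueness checks of one CRM campaign.

    Precision passes when ``chi2_c`` is strictly below the chi² critical
    value; trueness passes when the absolute bias is at most the
    expanded comparison uncertainty (boundary equality passes).
    """
    if sigma_w0 is None or sigma_w0 <= 0:
        raise ConfigurationError("sigma_w0 is a required supplied value (> 0)")
    if u_meas is None or u_meas < 0:
        raise ConfigurationError("u_meas is a required supplied value (>= 0)")
    chi2_c = precision_statistic(reps.sd, sigma_w0)
    threshold = chi2_threshold(reps.n, level)
    u_bcr = crm.standard_uncertainty
    diff = abs(reps.mean - crm.certified_value)
    bound = trueness_bound(k, u_meas, u_bcr)
    return ValidationResult(
        crm_name=crm.name,
        n=reps.n,
        mean=reps.mean,
        sd=reps.sd,
        certified_value=crm.certified_value,
        sigma_w0=sigma_w0,
        u_meas=u_meas,
        u_bcr=u_bcr,
        chi2_c=chi2_c,
        chi2_threshold=threshold,
        precision_pass=chi2_c < threshold,
        abs_diff=diff,
        trueness_bound=bound,
        k=k,
        level=level,
        trueness_pass=diff <= bound,
    )


# ---------------------------------------------------------------------------
# bundled CRM descriptors

def _data_path(name: str) -> Path:
    return Path(str(resources.files("fiberburden").joinpath("data", name)))


def bundled_crm_names() -> list[str]:
    """Names of CRM descriptors shipped with the package."""
    return ["bcr665", "bcr666"]


def load_crm(source: str | Path) -> tuple[CRMSpec, dict]:
    """Load a CRM descriptor from a JSON file or a bundled name.

    ``source`` may be ``"bcr665"`` / ``"bcr666"`` or a path to a JSON
    file with keys ``name, certified_value_mil_ffg,
    expanded_uncertainty_mil_ffg, t_factor, analyte`` and optionally a
    ``replicate_summary`` block (``n, mean, sd, sigma_w0, u_meas``).
    Returns the spec and the raw document (for the optional extras).
    """
    if isinstance(source, str) and source.lower() in bundled_crm_names():
        path = _data_path(f"{source.lower()}.json")
    else:
        path = Path(source)
    with open(path) as fh:
        doc = json.load(fh)
    spec = CRMSpec(
        name=doc["name"],
        certified_value=doc["certified_value_mil_ffg"],
        expanded_uncertainty=doc["expanded_uncertainty_mil_ffg"],
        t_factor=doc.get("t_factor", DEFAULT_T_FACTOR),
        analyte=doc.get("analyte", ""),
    )
    return spec, doc
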