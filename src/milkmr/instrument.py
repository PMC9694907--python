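"""Weighted genetic score for a single-SNP milk-consumption instrument.

The instrument is a lactase-persistence variant (rs4988235, upstream of
*LCT*): each milk-increasing allele raises self-reported milk intake by
roughly 17.1 g/day (95% CI 10.6-23.6) and explains about 2% of the
phenotypic variance in intake.  The genetic score multiplies the allele
dosage by this weight and divides by a reporting unit (50 g/day by
default), so that regression coefficients on the score are natively
interpretable per 50 g/day of genetically predicted milk consumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "InstrumentWeight",
    "DEFAULT_WEIGHT",
    "weighted_score",
    "variance_explained",
    "f_statistic",
    "se_from_ci",
]


def se_from_ci(low: float, high: float, level: float = 0.95) -> float:
    """Recover a standard error from a symmetric Wald confidence interval.

    Parameters
    ----------
    low, high
        Interval endpoints on the estimation scale (e.g. log-odds, g/day).
    level
        Confidence level of the interval, in (0, 1).

    Returns
    -------
    float
        ``(high - low) / (2 * z)`` with ``z`` the standard-normal quantile
        at ``(1 + level) / 2``, evaluated at full double precision.
    """
    if not (0.0 < level < 1.0):
        raise ValidationError(f"confidence level must be in (0,1), got {level}")
    if not (np.isfinite(low) and np.isfinite(high)):
        raise ValidationError("interval endpoints must be finite")
    if low >= high:
        raise ValidationError(f"interval is empty or inverted: ({low}, {high})")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (high - low) / (2.0 * z)


@dataclass(frozen=True)
class InstrumentWeight:
    """Published per-allele effect of the instrument SNP on milk intake.

    The default weight is the per-allele increase in milk consumption of
    17.1 g/day (95% CI 10.6-23.6) reported for rs4988235 in a European
    cohort; its standard error is recovered from the interval width.
    """

    snp_id: str = "rs4988235"
    effect_allele: str = "T"
    other_allele: str = "C"
    per_allele_effect: float = 17.1  # g/day per milk-increasing allele
    ci_low: float = 10.6
    ci_high: float = 23.6
    level: float = 0.95
    source: str = "published per-allele effect on milk intake"

    def __post_init__(self) -> None:
        if not (self.ci_low < self.per_allele_effect < self.ci_high):
            raise ValidationError(
                "point estimate must lie strictly inside its confidence interval: "
                f"{self.per_allele_effect} vs ({self.ci_low}, {self.ci_high})"
            )

    @property
    def se(self) -> float:
        """Standard error (g/day) implied by the confidence interval."""
        return se_from_ci(self.ci_low, self.ci_high, self.level)


DEFAULT_WEIGHT = InstrumentWeight()


def weighted_score(
    dosage: np.ndarray, weight: InstrumentWeight = DEFAULT_WEIGHT, unit_g: float = 50.0
) -> np.ndarray:
    """Per-person genetic score in units of ``unit_g`` g/day of predicted intake.

    ``score = dosage * per_allele_effect / unit_g``.  With the default
    50 g/day unit, a coefficient on this score reads as the effect per
    50 g/day of genetically predicted milk consumption.
    """
    if not (unit_g > 0) or not np.isfinite(unit_g):
        raise ValidationError(f"unit must be a positive finite number of g/day, got {unit_g}")
    d = np.asarray(dosage)
    if d.size and not np.isin(d, (0, 1, 2)).all():
        raise ValidationError("dosages must all be in {0, 1, 2}")
    return d.astype(float) * (weight.per_allele_effect / unit_g)


def variance_explained(score: np.ndarray, exposure: np.ndarray) -> float:
    """Fraction of exposure variance explained by the score.

    Computed as the squared Pearson correlation, which for a single
    regressor equals the R-squared of the simple linear regression of
    exposure on score.
    """
    s = np.asarray(score, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if s.shape != x.shape:
        raise ValidationError("score and exposure lengths differ")
    if s.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(s) == 0 or np.ptp(x) == 0:
        raise ValidationError("variance_explained is undefined for constant input")
    r = np.corrcoef(s, x)[0, 1]
    return float(r * r)


def f_statistic(r2: float, n: int) -> float:
    """Single-regressor instrument-strength F statistic.

    Uses the one-regressor identity ``F = r2 * (n - 2) / (1 - r2)``;
    values far above 10 indicate a strong instrument.
    """
    if not (0.0 <= r2 < 1.0):
        raise ValidationError(f"r2 must be in [0,1), got {r2}")
    if n <= 2:
        raise ValidationError(f"need n > 2, got {n}")
    return float(r2 * (n - 2) / (1.0 - r2))
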