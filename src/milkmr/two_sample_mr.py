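"""Single-instrument two-sample Mendelian randomization.

Given GWAS-style summary statistics for the SNP-exposure association
(g/day of milk per allele) and the SNP-outcome association (log-odds per
allele for disease outcomes), the causal effect of the exposure on the
outcome is estimated by the Wald ratio

    beta_MR = beta_outcome / beta_exposure,

with a delta-method standard error.  The first-order delta method treats
the exposure association as fixed (``se = se_out / |b_exp|``); the
second-order variant propagates its uncertainty as well.  Estimates are
rescaled to a 50 g/day increase in genetically predicted milk intake and
expressed as odds ratios with Wald confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

import numpy as np
from scipy import stats

from .exceptions import AnalysisError, HarmonizationError, ValidationError

__all__ = [
    "SnpSummaryStat",
    "WaldEstimate",
    "harmonize",
    "wald_ratio",
    "rescale",
    "to_or_ci",
    "mr_pipeline",
]

_NUCLEOTIDES = frozenset("ACGT")
_PALINDROMIC = (frozenset("AT"), frozenset("GC"))


@dataclass(frozen=True)
class SnpSummaryStat:
    """One SNP-trait association as printed in GWAS summary statistics.

    ``beta`` is the per-effect-allele association: g/day for a continuous
    exposure, log-odds (or SD units) for outcomes.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    n: Optional[int] = None
    n_case: Optional[int] = None
    n_control: Optional[int] = None
    unit: str = ""

    def __post_init__(self) -> None:
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        for allele in (ea, oa):
            if allele not in _NUCLEOTIDES:
                raise ValidationError(
                    f"allele {allele!r} is not a single-nucleotide label; "
                    "only biallelic SNPs are supported"
                )
        if ea == oa:
            raise ValidationError("effect and other allele must differ")
        if not (self.se > 0) or not np.isfinite(self.se):
            raise ValidationError(f"standard error must be positive and finite, got {self.se}")
        if not np.isfinite(self.beta):
            raise ValidationError("beta must be finite")
        if not self.unit:
            raise ValidationError("unit label must be non-empty")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))


class OrCi(NamedTuple):
    or_: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class WaldEstimate:
    """Wald-ratio MR estimate in outcome units per 50 g/day (or ``unit_g``)."""

    beta_mr: float
    se_mr: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    unit_g: float = 50.0


def _is_swapped_palindrome(a: SnpSummaryStat, b: SnpSummaryStat) -> bool:
    return a.alleles in _PALINDROMIC and a.alleles == b.alleles


def harmonize(
    exposure: SnpSummaryStat,
    outcome: SnpSummaryStat,
    assume_same_strand: bool = False,
) -> tuple[SnpSummaryStat, SnpSummaryStat]:
    """Align the outcome statistic to the exposure's effect allele.

    If the outcome reports the same effect allele the pair is returned
    unchanged; if the allele labels are swapped the outcome beta is
    negated.  A palindromic pair (A/T or G/C) with swapped labels is
    ambiguous — swapped labels on the same strand and identical labels on
    opposite strands are indistinguishable from these fields — and raises
    unless ``assume_same_strand=True`` is passed explicitly.
    """
    if exposure.snp_id != outcome.snp_id:
        raise HarmonizationError(
            f"cannot harmonize different SNPs: {exposure.snp_id} vs {outcome.snp_id}"
        )
    if exposure.alleles != outcome.alleles:
        raise HarmonizationError(
            f"allele sets disagree for {exposure.snp_id}: "
            f"{exposure.effect_allele}/{exposure.other_allele} vs "
            f"{outcome.effect_allele}/{outcome.other_allele}"
        )
    if exposure.effect_allele == outcome.effect_allele:
        return exposure, outcome
    # Swapped labels.
    if _is_swapped_palindrome(exposure, outcome) and not assume_same_strand:
        raise HarmonizationError(
            f"{exposure.snp_id} is palindromic "
            f"({exposure.effect_allele}/{exposure.other_allele}) with swapped labels; "
            "strand cannot be resolved from allele fields — pass "
            "assume_same_strand=True to flip the sign anyway"
        )
    flipped = replace(
        outcome,
        beta=-outcome.beta,
        effect_allele=outcome.other_allele,
        other_allele=outcome.effect_allele,
    )
    return exposure, flipped


def wald_ratio(
    exposure: SnpSummaryStat,
    outcome: SnpSummaryStat,
    method: str = "first_order",
) -> tuple[float, float]:
    """Wald-ratio estimate in outcome units per unit of exposure.

    ``beta = b_out / b_exp``.  ``first_order`` ignores the uncertainty of
    the exposure association (``se_out / |b_exp|``); ``second_order`` adds
    it: ``sqrt(se_out^2/b_exp^2 + b_out^2 se_exp^2 / b_exp^4)``.
    """
    if method not in ("first_order", "second_order"):
        raise ValidationError(f"unknown delta-method order: {method!r}")
    if exposure.effect_allele != outcome.effect_allele:
        raise ValidationError("statistics must be harmonized before forming the ratio")
    b_exp, b_out = exposure.beta, outcome.beta
    if b_exp == 0:
        raise AnalysisError("Wald ratio undefined: exposure beta is zero")
    beta = b_out / b_exp
    if method == "first_order":
        se = outcome.se / abs(b_exp)
    else:
        se = math.sqrt(
            outcome.se**2 / b_exp**2 + b_out**2 * exposure.se**2 / b_exp**4
        )
    return beta, se


def rescale(estimate: tuple[float, float], factor: float) -> tuple[float, float]:
    """Linearly rescale (beta, se); the z statistic (and p) are invariant."""
    if factor == 0 or not np.isfinite(factor):
        raise ValidationError(f"rescale factor must be finite and non-zero, got {factor}")
    beta, se = estimate
    return beta * factor, abs(se * factor)


def to_or_ci(beta: float, se: float, level: float = 0.95) -> OrCi:
    """Convert a log-odds estimate to OR, Wald CI and two-sided p.

    The normal quantile is used at full double precision (1.959963985...
    at the default level), not the rounded 1.96.
    """
    if not (se > 0) or not np.isfinite(se):
        raise ValidationError(f"standard error must be positive and finite, got {se}")
    if not (0.0 < level < 1.0):
        raise ValidationError(f"confidence level must be in (0,1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    or_ = math.exp(beta)
    ci_low = math.exp(beta - z * se)
    ci_high = math.exp(beta + z * se)
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return OrCi(or_, ci_low, ci_high, float(p))


def mr_pipeline(
    exposure: SnpSummaryStat,
    outcome: SnpSummaryStat,
    unit_g: float = 50.0,
    method: str = "first_order",
    assume_same_strand: bool = False,
) -> WaldEstimate:
    """Harmonize, form the Wald ratio, rescale to ``unit_g`` g/day, convert to OR.

    The exposure beta must be in g/day per allele, so the ratio is per
    g/day and multiplying by ``unit_g`` yields the effect per ``unit_g``
    g/day of genetically predicted intake.
    """
    exp_h, out_h = harmonize(exposure, outcome, assume_same_strand=assume_same_strand)
    beta, se = wald_ratio(exp_h, out_h, method=method)
    beta, se = rescale((beta, se), unit_g)
    or_, ci_low, ci_high, p = to_or_ci(beta, se)
    return WaldEstimate(
        beta_mr=beta,
        se_mr=se,
        or_=or_,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        method=method,
        unit_g=unit_g,
    )
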