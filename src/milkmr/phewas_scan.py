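"""Phenome-wide logistic scan of the genetic score with FDR control.

Each retained phecode is regressed (maximum-likelihood logistic fit) on
the weighted genetic score, adjusting for age, sex, BMI, assessment
center and ten genetic principal components by default.  Persons excluded
for a phenotype by its phecode exclusion range are dropped from that fit
only.  Two-sided Wald p-values are corrected across the whole scan by the
Benjamini-Hochberg step-up procedure.  Sensitivity variants drop the BMI
adjustment or stratify on overweight status (BMI < 25 vs >= 25 kg/m^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import AnalysisError, ValidationError
from .phecode_engine import CASE, EXCLUDED, PhenotypeMatrix, filter_min_cases
from .two_sample_mr import to_or_ci

__all__ = [
    "ScanConfig",
    "FitResult",
    "fit_logistic",
    "run_phewas",
    "bh_fdr",
    "stratified_scan",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "bmi", "center") + tuple(f"pc{k}" for k in range(1, 11))

RESULT_COLUMNS = [
    "phecode", "label", "category", "n_case", "n_control",
    "beta", "se", "or", "ci_low", "ci_high", "p", "q", "significant",
]

# Coefficients beyond this magnitude on the 50 g/day score scale indicate
# (quasi-)separation rather than a meaningful estimate.
_SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class ScanConfig:
    """Scan settings: covariate set, BMI handling, case filter and FDR level."""

    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    include_bmi: bool = True
    min_cases: int = 200
    fdr_level: float = 0.05
    bmi_cut: float = 25.0  # kg/m^2, overweight threshold for stratification

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_level < 1.0):
            raise ValidationError(f"FDR level must be in (0,1), got {self.fdr_level}")
        if self.min_cases < 1:
            raise ValidationError(f"min_cases must be >= 1, got {self.min_cases}")


@dataclass(frozen=True)
class FitResult:
    """Score coefficient from one logistic fit (log-odds per 50 g/day)."""

    beta: float
    se: float
    p: float
    converged: bool
    note: str = ""


def build_design(
    covariates: Optional[pd.DataFrame],
    names: Sequence[str] = (),
    include_bmi: bool = True,
) -> pd.DataFrame:
    """Numeric design block for the requested covariates.

    Categorical columns (e.g. assessment center) enter as indicator
    contrasts with the most frequent level as reference (ties broken by
    label order); numeric columns enter as-is.
    """
    frames: list[pd.DataFrame] = []
    for name in names:
        if name == "bmi" and not include_bmi:
            continue
        if covariates is None or name not in covariates.columns:
            raise ValidationError(f"covariate {name!r} not present in the covariate table")
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            frames.append(col.astype(float).to_frame(name))
        else:
            counts = col.value_counts()
            reference = sorted(counts.index[counts == counts.max()])[0]
            levels = [lv for lv in sorted(col.unique()) if lv != reference]
            dummies = pd.DataFrame(
                {f"{name}[{lv}]": (col == lv).astype(float) for lv in levels},
                index=col.index,
            )
            frames.append(dummies)
    if not frames:
        return pd.DataFrame(index=covariates.index if covariates is not None else None)
    return pd.concat(frames, axis=1)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # Identify offending columns from the QR diagonal.
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        bad = [X.columns[j] for j in np.flatnonzero(diag <= tol)]
        raise ValidationError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_logistic(
    status: np.ndarray,
    score: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    covariate_names: Sequence[str] = (),
    include_bmi: bool = True,
) -> FitResult:
    """Maximum-likelihood logistic fit of case status on the genetic score.

    Returns the score coefficient, its observed-information standard
    error and the two-sided Wald normal p-value.  Non-convergence and
    (quasi-)separation are flagged in the result instead of raising;
    rank deficiency raises and names the collinear columns.
    """
    y = np.asarray(status, dtype=float)
    s = np.asarray(score, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("status and score lengths differ")
    if not ((y == 0) | (y == 1)).all():
        raise ValidationError("status must be binary case/control indicators")
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise AnalysisError("need at least one case and one control")
    design = build_design(covariates, covariate_names, include_bmi=include_bmi)
    X = pd.DataFrame({"const": np.ones_like(s), "score": s})
    if len(design.columns):
        X = pd.concat([X, design.reset_index(drop=True)], axis=1)
    _check_full_rank(X)
    try:
        res = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    except Exception as exc:  # perfect separation raises in some statsmodels versions
        return FitResult(np.nan, np.nan, np.nan, converged=False, note=f"fit failed: {exc}")
    beta = float(res.params[1])
    se = float(res.bse[1])
    converged = bool(getattr(res, "converged", True))
    note = ""
    if abs(beta) > _SEPARATION_BETA:
        converged, note = False, "separation suspected (|beta| > 15)"
    elif not converged:
        note = "IRLS did not converge in 100 iterations"
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else np.nan
    return FitResult(beta, se, p, converged=converged, note=note)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    After sorting ascending, ``q_(i) = min_{j >= i} m * p_(j) / j``,
    capped at 1.  Significance at level alpha is ``q <= alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_phewas(
    matrix: PhenotypeMatrix,
    score: np.ndarray,
    covariates: Optional[pd.DataFrame],
    config: ScanConfig = ScanConfig(),
) -> pd.DataFrame:
    """Scan every retained phecode against the genetic score.

    The minimum-case filter is (re-)applied, each phenotype is fitted on
    its non-excluded persons, and BH q-values are computed over the full
    scan.  Per-phenotype failures are flagged in the output (NaN beta, a
    note) without aborting the scan.  Output rows are ordered by phecode,
    so repeated runs on the same inputs are identical.
    """
    matrix = filter_min_cases(matrix, config.min_cases)
    if not matrix.phecodes:
        raise AnalysisError(
            f"no phenotypes with at least {config.min_cases} cases; nothing to scan"
        )
    s = np.asarray(score, dtype=float)
    if s.size != matrix.n_individuals:
        raise ValidationError("score length does not match the phenotype matrix")
    rows = []
    for phecode in sorted(matrix.phecodes, key=str):
        col = matrix.status[phecode].to_numpy()
        keep = col != EXCLUDED
        y = (col[keep] == CASE).astype(float)
        cov = covariates.loc[keep] if covariates is not None else None
        meta = matrix.meta.loc[phecode]
        try:
            fit = fit_logistic(
                y,
                s[keep],
                cov.reset_index(drop=True) if cov is not None else None,
                config.covariates,
                include_bmi=config.include_bmi,
            )
        except (ValidationError, AnalysisError) as exc:
            logger.warning("phecode %s: fit failed (%s)", phecode, exc)
            fit = FitResult(np.nan, np.nan, np.nan, converged=False, note=str(exc))
        rows.append(
            {
                "phecode": str(phecode),
                "label": meta["label"],
                "category": meta["category"],
                "n_case": int(meta["n_case"]),
                "n_control": int(meta["n_control"]),
                "beta": fit.beta,
                "se": fit.se,
                "p": fit.p,
                "converged": fit.converged,
                "note": fit.note,
            }
        )
    results = pd.DataFrame(rows)
    ok = results["p"].notna() & results["converged"]
    results["q"] = np.nan
    if ok.any():
        results.loc[ok, "q"] = bh_fdr(results.loc[ok, "p"].to_numpy())
    results["significant"] = results["q"].le(config.fdr_level).fillna(False)
    with np.errstate(invalid="ignore"):
        ors = [
            to_or_ci(b, e) if np.isfinite(b) and e > 0 else (np.nan, np.nan, np.nan, np.nan)
            for b, e in zip(results["beta"], results["se"])
        ]
    results[["or", "ci_low", "ci_high"]] = [(o[0], o[1], o[2]) for o in ors]
    return results[RESULT_COLUMNS + ["converged", "note"]]


def stratified_scan(
    matrix: PhenotypeMatrix,
    score: np.ndarray,
    covariates: pd.DataFrame,
    config: ScanConfig = ScanConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Independent scans of the non-overweight and overweight strata.

    Splits at ``config.bmi_cut`` (BMI < cut vs >= cut), re-applies the
    minimum-case filter within each stratum and removes BMI from the
    within-stratum covariates.
    """
    if covariates is None or "bmi" not in covariates.columns:
        raise ValidationError("BMI must be present in the covariates for a stratified scan")
    s = np.asarray(score, dtype=float)
    bmi = covariates["bmi"].to_numpy(dtype=float)
    low = bmi < config.bmi_cut
    if low.sum() == 0 or (~low).sum() == 0:
        raise AnalysisError(f"empty BMI stratum at cut {config.bmi_cut} kg/m^2")
    names = tuple(n for n in config.covariates if n != "bmi")
    sub_config = replace(config, covariates=names, include_bmi=False)
    out = []
    for mask in (low, ~low):
        ids = matrix.status.index[mask]
        sub = matrix.subset(ids)
        out.append(
            run_phewas(sub, s[mask], covariates.loc[mask].reset_index(drop=True), sub_config)
        )
    return out[0], out[1]
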