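"""Synthetic biobank cohorts with the statistical structure the scan assumes.

Real MR-PheWAS inputs (biobank genotypes, registry diagnoses, GWAS summary
statistics) are access-controlled, so this module generates cohorts with
the same generative structure: one biallelic instrument SNP in
Hardy-Weinberg equilibrium whose dosage shifts a continuous milk-intake
exposure by a fixed number of g/day per allele and explains a target
fraction of exposure variance; binary disease phenotypes drawn from
logistic models whose log-odds move by a chosen amount per 50 g/day of
true exposure; and long-format ICD-9/ICD-10 diagnosis records emitted for
cases so the phecode mapping stage can be exercised end to end.

Randomness is controlled by one cohort seed; every operation draws from
its own deterministic sub-stream, so adding an outcome never perturbs the
genotypes or the exposure.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import AnalysisError, ValidationError
from .instrument import DEFAULT_WEIGHT, InstrumentWeight
from .phecode_engine import PhecodeMap, normalize_icd

__all__ = [
    "OutcomeSpec",
    "CohortConfig",
    "SimulatedCohort",
    "generate_genotypes",
    "generate_covariates",
    "generate_exposure",
    "generate_outcomes",
    "emit_icd_records",
    "generate_summary_stats",
    "simulate_cohort",
]

logger = logging.getLogger(__name__)

# Sub-stream labels: operations draw from SeedSequence(seed, spawn_key=(label, ...)).
_STREAM_GENOTYPES = 0
_STREAM_COVARIATES = 1
_STREAM_EXPOSURE = 2
_STREAM_OUTCOMES = 3
_STREAM_ICD = 4

PHENOTYPE_PREFIX = "case_"


def _substream(seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(stream, *extra)))


def _phecode_stream_key(phecode: str) -> int:
    # Stable per-phecode key so outcome sub-streams are independent of
    # the order in which outcomes are listed.
    return zlib.crc32(str(phecode).encode("utf-8"))


@dataclass(frozen=True)
class OutcomeSpec:
    """Generative model of one binary phenotype.

    ``log_or_per_50g`` is the causal log-odds per 50 g/day of *true*
    exposure; the pipeline's job is to recover it.  ``covariate_log_ors``
    maps covariate names to log-odds per unit of the (sample-centered)
    covariate.  ``icd_codes`` lists the (code, vocabulary) pairs emitted
    for cases.
    """

    phecode: str
    baseline_prevalence: float
    log_or_per_50g: float = 0.0
    covariate_log_ors: Mapping[str, float] = field(default_factory=dict)
    icd_codes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise ValidationError(
                f"baseline prevalence must be in (0,1), got {self.baseline_prevalence} "
                f"for phecode {self.phecode}"
            )
        if not self.icd_codes:
            raise ValidationError(f"outcome {self.phecode} lists no ICD codes")
        object.__setattr__(self, "icd_codes", tuple((str(c), str(v)) for c, v in self.icd_codes))


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one simulated cohort.

    Defaults mirror the study conditions the pipeline targets: a
    lactase-persistence-style instrument with a per-allele effect of
    17.1 g/day explaining 2% of exposure variance at an effect-allele
    frequency of 0.70, in a middle-aged cohort (ages 40-69, 53.7% female)
    with BMI ~ Normal(27, 4.5), five assessment centers and ten genetic
    principal components.  ``exposure_mean`` defaults to 200 g/day, a
    typical self-reported milk intake in European cohorts.
    """

    n_individuals: int
    seed: int = 0
    effect_allele_freq: float = 0.70
    per_allele_effect: float = 17.1  # g/day per allele
    target_r2: float = 0.02
    exposure_mean: float = 200.0  # g/day
    covariate_effects: Mapping[str, float] = field(default_factory=dict)  # g/day per unit
    noise_sd: Optional[float] = None  # g/day; overrides the target_r2 calibration
    bmi_exposure_effect: float = 0.0  # kg/m^2 per g/day of exposure (mediation)
    outcome_specs: tuple[OutcomeSpec, ...] = ()
    # Covariate distributions (all overridable).
    age_low: float = 40.0
    age_high: float = 69.0
    sex_female_frac: float = 0.537
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    n_centers: int = 5
    n_pcs: int = 10

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValidationError(f"need at least 2 individuals, got {self.n_individuals}")
        if not (0.0 < self.effect_allele_freq < 1.0):
            raise ValidationError(
                f"effect allele frequency must be in (0,1), got {self.effect_allele_freq}"
            )
        if not (0.0 < self.target_r2 < 1.0):
            raise ValidationError(f"target r2 must be in (0,1), got {self.target_r2}")
        if not (0.0 < self.sex_female_frac < 1.0):
            raise ValidationError("sex_female_frac must be in (0,1)")
        object.__setattr__(self, "outcome_specs", tuple(self.outcome_specs))


def generate_genotypes(n: int, effect_allele_freq: float, seed: int) -> np.ndarray:
    """Effect-allele dosages under Hardy-Weinberg equilibrium.

    Dosages are Binomial(2, freq) per person; the degenerate frequencies
    0 and 1 are allowed here (all-0 / all-2 cohorts) and rejected later
    where a polymorphic instrument is required.
    """
    if n < 1:
        raise ValidationError(f"need n >= 1, got {n}")
    f = float(effect_allele_freq)
    if not np.isfinite(f) or not (0.0 <= f <= 1.0):
        raise ValidationError(f"effect allele frequency must be in [0,1], got {effect_allele_freq}")
    rng = _substream(seed, _STREAM_GENOTYPES)
    return rng.binomial(2, f, size=int(n)).astype(np.int8)


def generate_covariates(config: CohortConfig) -> pd.DataFrame:
    """Baseline covariate table: age, sex, BMI, assessment center, PCs.

    age ~ Uniform(age_low, age_high); sex ~ Bernoulli(female fraction),
    coded 1 = female; bmi ~ Normal(bmi_mean, bmi_sd); center uniform over
    ``n_centers`` labelled levels; PCs iid standard normal.
    """
    rng = _substream(config.seed, _STREAM_COVARIATES)
    n = config.n_individuals
    cov = pd.DataFrame(
        {
            "age": rng.uniform(config.age_low, config.age_high, n),
            "sex": (rng.random(n) < config.sex_female_frac).astype(np.int8),
            "bmi": rng.normal(config.bmi_mean, config.bmi_sd, n),
            "center": pd.Categorical.from_codes(
                rng.integers(0, config.n_centers, n),
                categories=[f"C{i + 1}" for i in range(config.n_centers)],
            ).astype(str),
        },
        index=pd.RangeIndex(n, name="person_id"),
    )
    for k in range(1, config.n_pcs + 1):
        cov[f"pc{k}"] = rng.normal(0.0, 1.0, n)
    return cov


def _covariate_contribution(
    covariates: Optional[pd.DataFrame], effects: Mapping[str, float], n: int
) -> np.ndarray:
    """Sum of per-unit effects on sample-centered numeric covariates."""
    contrib = np.zeros(n)
    for name, eff in effects.items():
        if covariates is None or name not in covariates.columns:
            raise ValidationError(f"covariate {name!r} has an effect but is not in the table")
        col = covariates[name]
        if not pd.api.types.is_numeric_dtype(col):
            raise ValidationError(f"covariate {name!r} is not numeric; categorical effects unsupported")
        contrib += float(eff) * (col.to_numpy(dtype=float) - float(col.mean()))
    return contrib


def generate_exposure(
    genotypes: np.ndarray,
    covariates: Optional[pd.DataFrame],
    config: CohortConfig,
) -> np.ndarray:
    """Continuous exposure (g/day) with a calibrated instrument R-squared.

    exposure = mean + per_allele_effect * dosage + covariate effects +
    Gaussian noise.  The noise variance is solved analytically so the
    SNP's expected variance explained equals ``target_r2``: with genetic
    variance ``v_g = effect^2 * 2 f (1-f)`` and covariate-effect variance
    ``v_c``, ``var(noise) = v_g (1 - r2) / r2 - v_c`` (for zero covariate
    effects this is ``effect^2 * 2 f (1-f) (1-r2)/r2``).  Negative draws
    are floored at 0 g/day and the truncation rate is logged.
    """
    d = np.asarray(genotypes, dtype=float)
    if covariates is not None and len(covariates) != d.size:
        raise ValidationError("genotype and covariate lengths differ")
    if config.noise_sd is None and np.ptp(d) == 0:
        raise ValidationError(
            "target r2 is incompatible with zero genetic variance: the realized "
            "dosages are constant; set noise_sd explicitly for a null instrument"
        )
    contrib = _covariate_contribution(covariates, config.covariate_effects, d.size)
    if config.noise_sd is not None:
        if not (config.noise_sd > 0):
            raise ValidationError(f"noise_sd must be positive, got {config.noise_sd}")
        var_noise = float(config.noise_sd) ** 2
    else:
        f = config.effect_allele_freq
        var_g = config.per_allele_effect**2 * 2.0 * f * (1.0 - f)
        if var_g == 0.0:
            raise ValidationError(
                "target r2 is incompatible with zero genetic variance (allele frequency 0 "
                "or 1, or a null per-allele effect); set noise_sd explicitly instead"
            )
        var_c = float(np.var(contrib))
        var_noise = var_g * (1.0 - config.target_r2) / config.target_r2 - var_c
        if var_noise <= 0:
            raise ValidationError(
                "covariate effects alone exceed the residual variance implied by target_r2; "
                "lower the covariate effects or the target r2"
            )
    rng = _substream(config.seed, _STREAM_EXPOSURE)
    latent = (
        config.exposure_mean
        + config.per_allele_effect * d
        + contrib
        + rng.normal(0.0, math.sqrt(var_noise), d.size)
    )
    exposure = np.maximum(latent, 0.0)
    trunc = float(np.mean(latent < 0))
    if trunc > 0:
        logger.info("generate_exposure: floored %.3f%% of draws at 0 g/day", 100 * trunc)
    return exposure


def _solve_intercept(lin: np.ndarray, prevalence: float) -> float:
    """Intercept making the marginal case probability equal ``prevalence``.

    Root of mean(expit(alpha + lin)) - prevalence, found by Brent's
    method to 1e-8; the mean is monotone increasing in alpha so the wide
    bracket always works.
    """
    def gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + lin))) - prevalence

    lo, hi = -40.0, 40.0
    return float(brentq(gap, lo, hi, xtol=1e-8))


def generate_outcomes(
    exposure: np.ndarray,
    covariates: Optional[pd.DataFrame],
    specs: Sequence[OutcomeSpec],
    seed: int,
) -> pd.DataFrame:
    """Binary phenotypes from per-outcome logistic models.

    Case indicators are Bernoulli(expit(alpha + theta * exposure / 50 +
    covariate terms)) with the intercept alpha solved so the marginal
    prevalence equals ``baseline_prevalence`` at theta = 0 (i.e. over the
    covariate-only linear predictor).  Each outcome draws from its own
    sub-stream keyed by phecode, so the realisations are invariant to the
    order and number of other outcomes.
    """
    specs = list(specs)
    if not specs:
        raise ValidationError("no outcome specs given")
    x = np.asarray(exposure, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("exposure contains non-finite values")
    out = {}
    index = covariates.index if covariates is not None else pd.RangeIndex(x.size, name="person_id")
    for spec in specs:
        lin_cov = _covariate_contribution(covariates, spec.covariate_log_ors, x.size)
        alpha = _solve_intercept(lin_cov, spec.baseline_prevalence)
        p = expit(alpha + spec.log_or_per_50g * x / 50.0 + lin_cov)
        rng = _substream(seed, _STREAM_OUTCOMES, _phecode_stream_key(spec.phecode))
        out[spec.phecode] = (rng.random(x.size) < p).astype(np.int8)
    return pd.DataFrame(out, index=index)


def emit_icd_records(
    phenotypes: pd.DataFrame,
    pmap: PhecodeMap,
    seed: int,
    specs: Optional[Sequence[OutcomeSpec]] = None,
) -> pd.DataFrame:
    """Long-format diagnosis records (person_id, code, vocabulary) for cases.

    Every case of a phecode receives at least one record drawn from that
    outcome's ICD codes (one guaranteed plus each remaining code with
    probability 1/2, so both vocabularies appear across the cohort when
    both are listed); controls receive none.  Mapping the records back
    through the phecode engine therefore recovers the case sets exactly.
    """
    code_pool: dict[str, list[tuple[str, str]]] = {}
    if specs is not None:
        by_phecode = {s.phecode: s for s in specs}
    else:
        by_phecode = {}
    for phecode in phenotypes.columns:
        spec = by_phecode.get(str(phecode))
        if spec is not None:
            codes = []
            for raw, vocab in spec.icd_codes:
                canon = normalize_icd(raw, vocab)
                row = pmap.table[
                    (pmap.table["icd_code"] == canon) & (pmap.table["vocabulary"] == vocab)
                ]
                if row.empty or row["phecode"].iloc[0] != str(phecode):
                    raise ValidationError(
                        f"ICD code {raw!r} ({vocab}) is not mapped to phecode {phecode} in the map"
                    )
                codes.append((canon, vocab))
        else:
            rows = pmap.codes_for(str(phecode))
            codes = list(rows.itertuples(index=False, name=None))
        if not codes:
            raise ValidationError(f"phecode {phecode} has no ICD codes in the map")
        code_pool[str(phecode)] = codes

    persons: list = []
    out_codes: list[str] = []
    out_vocab: list[str] = []
    for phecode in sorted(phenotypes.columns, key=str):
        codes = code_pool[str(phecode)]
        case_ids = phenotypes.index[phenotypes[phecode].to_numpy() == 1]
        if len(case_ids) == 0:
            continue
        rng = _substream(seed, _STREAM_ICD, _phecode_stream_key(str(phecode)))
        m = len(codes)
        first = rng.integers(0, m, size=len(case_ids))
        extra = rng.random((len(case_ids), m)) < 0.5
        for i, pid in enumerate(case_ids):
            chosen = set(np.flatnonzero(extra[i]))
            chosen.add(int(first[i]))
            for k in sorted(chosen):
                persons.append(pid)
                out_codes.append(codes[k][0])
                out_vocab.append(codes[k][1])
    records = pd.DataFrame({"person_id": persons, "code": out_codes, "vocabulary": out_vocab})
    return records.sort_values(["person_id", "vocabulary", "code"], kind="mergesort").reset_index(
        drop=True
    )


def generate_summary_stats(
    cohort: pd.DataFrame,
    phecode: str,
    weight: InstrumentWeight = DEFAULT_WEIGHT,
) -> tuple:
    """Per-allele GWAS-style summary statistics from an individual-level cohort.

    Returns a pair of :class:`~milkmr.two_sample_mr.SnpSummaryStat`: the
    exposure statistic is the slope/SE of the linear regression of
    exposure on dosage (g/day per allele); the outcome statistic is the
    log-OR/SE of the logistic regression of case status on dosage.
    """
    from .two_sample_mr import SnpSummaryStat  # local import to avoid a cycle

    for col in ("dosage", "exposure"):
        if col not in cohort.columns:
            raise ValidationError(f"cohort table is missing column {col!r}")
    pheno_col = PHENOTYPE_PREFIX + str(phecode)
    if pheno_col not in cohort.columns:
        raise ValidationError(f"phenotype column {pheno_col!r} not present in cohort")
    d = cohort["dosage"].to_numpy(dtype=float)
    if np.unique(d).size < 2:
        raise AnalysisError("both genotype classes must be represented to estimate per-allele effects")
    y = cohort[pheno_col].to_numpy(dtype=float)
    n_case, n_control = int(y.sum()), int((1 - y).sum())
    if n_case == 0:
        raise AnalysisError(f"phenotype {phecode} has zero cases")
    if n_control == 0:
        raise AnalysisError(f"phenotype {phecode} has zero controls")

    X = sm.add_constant(d)
    ols = sm.OLS(cohort["exposure"].to_numpy(dtype=float), X).fit()
    exposure_stat = SnpSummaryStat(
        snp_id=weight.snp_id,
        effect_allele=weight.effect_allele,
        other_allele=weight.other_allele,
        beta=float(ols.params[1]),
        se=float(ols.bse[1]),
        n=len(cohort),
        unit="g/day per allele",
    )
    logit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    outcome_stat = SnpSummaryStat(
        snp_id=weight.snp_id,
        effect_allele=weight.effect_allele,
        other_allele=weight.other_allele,
        beta=float(logit.params[1]),
        se=float(logit.bse[1]),
        n=len(cohort),
        n_case=n_case,
        n_control=n_control,
        unit="log-odds per allele",
    )
    return exposure_stat, outcome_stat


@dataclass(frozen=True)
class SimulatedCohort:
    """One simulated cohort: wide per-person table plus ICD records."""

    cohort: pd.DataFrame
    records: pd.DataFrame
    config: CohortConfig


def simulate_cohort(config: CohortConfig, pmap: Optional[PhecodeMap] = None) -> SimulatedCohort:
    """Run the full generative model for one cohort.

    Produces a wide table (person_id index; dosage, exposure, covariates,
    one ``case_<phecode>`` column per outcome) and, when a phecode map is
    given, the long-format ICD records for all cases.  BMI mediation
    (``bmi_exposure_effect`` != 0) shifts BMI by that many kg/m^2 per
    g/day of centered exposure after the exposure is drawn, turning BMI
    into a mediator between the instrument and any BMI-affected outcome.
    """
    genotypes = generate_genotypes(config.n_individuals, config.effect_allele_freq, config.seed)
    covariates = generate_covariates(config)
    exposure = generate_exposure(genotypes, covariates, config)
    if config.bmi_exposure_effect != 0.0:
        covariates = covariates.copy()
        covariates["bmi"] = covariates["bmi"] + config.bmi_exposure_effect * (
            exposure - float(np.mean(exposure))
        )
    cohort = covariates.copy()
    cohort.insert(0, "dosage", genotypes)
    cohort.insert(1, "exposure", exposure)
    records = pd.DataFrame(columns=["person_id", "code", "vocabulary"])
    if config.outcome_specs:
        phenotypes = generate_outcomes(exposure, covariates, config.outcome_specs, config.seed)
        for phecode in phenotypes.columns:
            cohort[PHENOTYPE_PREFIX + str(phecode)] = phenotypes[phecode]
        if pmap is not None:
            records = emit_icd_records(phenotypes, pmap, config.seed, config.outcome_specs)
    return SimulatedCohort(cohort=cohort, records=records, config=config)
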