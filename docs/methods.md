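# Methods

## Generative model of the synthetic biobank

Each cohort of `n` individuals is drawn as follows.

**Genotype.** The instrument SNP's effect-allele dosage is
`d_i ~ Binomial(2, f)` (Hardy–Weinberg equilibrium), with effect-allele
frequency `f = 0.70` by default — an approximate European frequency for
the milk-increasing lactase-persistence allele, stated as an assumption
(the frequency in the motivating cohorts is not published) and
user-overridable.

**Exposure.** Milk intake in g/day is

```
x_i = μ + β·d_i + Σ_c γ_c·(c_i − c̄) + ε_i,   ε_i ~ N(0, σ²),  x_i ← max(x_i, 0)
```

with per-allele effect `β = 17.1` g/day. The noise variance is solved
analytically so the instrument's expected variance explained equals the
target `r² = 0.02`: with genetic variance `v_g = β²·2f(1−f)` and
covariate-effect variance `v_c`, `σ² = v_g(1−r²)/r² − v_c` (for zero
covariate effects, `σ = β·sqrt(2f(1−f)(1−r²)/r²) ≈ 77.6` g/day). The
exposure distribution itself is not published; the default mean
`μ = 200` g/day is chosen as a typical self-reported milk intake in
European cohorts, and has the practical consequence that the floor at
0 g/day truncates only ≈0.2–0.5% of draws, so it does not materially
bias the per-allele slope. The truncation rate is logged. With a null
instrument (`β = 0`) the calibration is undefined and `noise_sd` must be
given explicitly. Tests of the mean exposure use the closed-form
truncated-normal expectation `E[max(0, N(μ_d, σ))] = μ_d Φ(μ_d/σ) +
σ φ(μ_d/σ)` per dosage class, HWE-weighted, as the oracle.

**Covariates.** age ~ Uniform(40, 69) years; sex ~ Bernoulli(0.537)
(1 = female); BMI ~ Normal(27, 4.5) kg/m²; assessment center uniform over
5 labelled levels; 10 genetic PCs iid standard normal. All defaults are
overridable. Setting `bmi_exposure_effect` (kg/m² per g/day) makes BMI a
*mediator*: after the exposure is drawn, BMI is shifted by that amount
per centered g/day, which is how the BMI-adjustment sensitivity analysis
is exercised with a known generative direction.

**Outcomes.** Each binary phenotype is
`y_i ~ Bernoulli(expit(α + θ·x_i/50 + Σ γ_c(c_i − c̄)))`, where `θ` is
the causal log-odds per 50 g/day the pipeline must recover. The
intercept is solved by Brent root-finding (tolerance 1e-8) so that the
*marginal* prevalence over the covariate-only predictor (θ = 0) equals
`baseline_prevalence`; with θ ≠ 0 the realised prevalence therefore
deviates from the baseline by design — `baseline_prevalence` is the
no-effect prevalence.

**ICD records.** Every case receives one guaranteed diagnosis code drawn
from the outcome's ICD list plus each remaining code with probability
1/2, mixing ICD-9 and ICD-10 when both are listed; controls receive
none. Mapping the records back through the phecode engine reproduces the
case matrix exactly, which the tests assert.

**Randomness.** One cohort seed; every operation draws from its own
`SeedSequence` sub-stream, and each outcome's stream is keyed by a CRC of
its phecode string, so adding or reordering outcomes never perturbs
genotypes, exposure or the other outcomes. Identical configuration and
seed give byte-identical output files.

### What the generator does and does not emulate

It reproduces the statistical structure the estimators assume: HWE
genotypes, a linear instrument–exposure relation with calibrated R², and
logistic outcome models with registry-style ICD records. It has no LD or
multi-SNP genotypes, no relatedness, no genotyping error, no
population stratification (PCs are pure noise), no secular/registry
coding artefacts, and no time-to-event structure. Passing tests
therefore demonstrate correctness of the estimators under their assumed
model, not robustness to the messiness of real biobank data.

## Phecode engine

ICD codes are canonicalised (uppercase, dot stripped); a person is a
case on a single mapped record (the single-occurrence rule; whether the
original analyses required multiple occurrences is not described).
Phecodes are compared as strings — never as floats — and their
dotted-decimal values are parsed only to evaluate exclusion-range
membership. Exclusion semantics: a non-case of phecode P who is a case
of another phecode inside P's `exclude_low–exclude_high` interval is
"excluded" (dropped from P's fits) rather than a control; maps without
range columns simply have no exclusions. A range that fails to cover its
own phecode is widened with a warning. Unmapped ICD codes are counted
and logged, not fatal. Sex-restricted phecodes are supported through an
optional map column (the bundled miniature map leaves it empty). The
minimum-case filter retains phenotypes with ≥ 200 cases (inclusive).

## Scan

Logistic fits use iteratively reweighted least squares (statsmodels GLM,
binomial family) with tolerance 1e-8 and at most 100 iterations; the
reported p is the two-sided Wald normal test of the score coefficient
against the observed-information SE. Assessment center enters as
indicator contrasts with the most frequent level as reference (ties
broken by label order). The design matrix is rank-checked first and rank
deficiency raises an error naming the collinear columns; non-convergence
and (quasi-)separation — detected as |β| > 15 on the 50 g/day scale —
are flagged in the output row rather than aborting the scan. Excluded
persons are dropped per phenotype, not globally. BH-FDR is computed once
over the full scan (all retained phecodes jointly), not per category;
q-values follow the step-up rule exactly and are cross-checked against a
brute-force O(m²) transcription and statsmodels. In the stratified scan
the minimum-case filter is re-applied within each stratum and BMI is
removed from the within-stratum covariates.

## Two-sample MR

Harmonization aligns the outcome's effect allele to the exposure's:
matching labels pass through, swapped labels negate the outcome beta, and
disagreeing allele sets raise. A palindromic pair (A/T, G/C) with
swapped labels is ambiguous from these fields alone and requires an
explicit `assume_same_strand=True` override. The default delta method is
**first order** (`se = se_out/|β_exp|`), the common single-SNP
convention — and the one consistent with published tables in which many
outcomes with different β_out share the same printed SE; the
second-order form `sqrt(se_out²/β² + β_out²·se_exp²/β⁴)` is available by
flag. The second-order SE is a good approximation only for strong
instruments: against a 10⁶-draw parametric bootstrap it is within 2% at
instrument z ≈ 10, but about 8% below the empirical SD of the ratio at
z ≈ 5 (with λ = se/β ≈ 0.19, the neglected higher-order moments of 1/β̂
are no longer small). The bootstrap comparison in the acceptance tests
is therefore run at z = 10.

## Reporting and rounding

Scaling to 50 g/day is applied to the *score* before regression (so scan
betas are natively per 50 g/day) and to the Wald ratio after division;
the two are algebraically identical for a one-SNP score. Display
rounding: OR and CI to 2 decimals with ties away from zero, betas/SEs to
3 decimals, p in scientific notation with 3 significant digits; the
normal quantile is used at full double precision (1.959963985…), never
1.96. Full-precision values are always retained in the TSVs.

When checking conversions of *published* rounded (beta, SE) pairs, the
OR point estimates reproduce the printed values exactly at 2-decimal
rounding. CI endpoints are checked for consistency under worst-case
propagation of the inputs' own 3-decimal rounding (corner evaluation at
beta ± 0.0005, se ± 0.0005, plus the half-ULP printing slack): two
published lower bounds lie ≈5×10⁻⁵ past the 0.865 rounding boundary, so
exact round-trip equality from the rounded inputs is not mathematically
attainable for them, while the consistency check is exact in the sense
that some input pair rounding to the printed one yields the printed
bound. Printed p-values are likewise not reproducible from rounded
inputs and are not targeted.

## Instrument-strength note

The one-regressor identity `F = R²(n−2)/(1−R²)` is implemented. At
R² = 2.5% and n = 339,197 it gives F ≈ 8,697; the F ≈ 1055 sometimes
quoted alongside those numbers for this instrument is not reproducible
under any standard one-regressor definition (it may refer to a subsample
or another statistic) and is not targeted.

## Problem sizes used in the checks

Chosen as the package's own precision/cost trade-offs: parameter
recovery uses 200 cohorts of n = 20,000 for the per-allele effect
(Monte-Carlo SE of the mean ≈ 0.06 g/day against a ±0.5 band) and 100
seeds of n = 200,000 for the θ = −0.12 recovery (MC SE ≈ 0.004 against
±0.01); recovery fits adjust for age, sex and BMI, which is sufficient
because the default generator gives covariates no outcome effects. Null
calibration uses 100 simulated scans × 20 phenotypes at n = 2,000
(type-I over the first 1,000 fits; scan-level FDR over the 100 scans
within 3 MC SEs of nominal). The bootstrap oracle uses 10⁶ draws. The
bundled analysis study uses one 60,000-person cohort.

## Known limitations

Single biallelic SNP only — no multi-variant scores and no
pleiotropy-robust estimators (IVW, MR-Egger, weighted median), which
need multiple instruments; no nonlinear exposure–outcome models; no
relatedness correction in the scan (the design assumes unrelated
individuals); the bundled phecode map is a 30-code miniature, though
full user-supplied maps in the same schema load and validate.
Continuous (SD-unit) outcomes pass through the Wald machinery
structurally, but OR conversion is only meaningful for binary outcomes.
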