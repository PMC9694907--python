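# milkmr — phenome-wide Mendelian randomization of milk consumption

`milkmr` is a tested re-implementation of a phenome-wide Mendelian
randomization (MR-PheWAS) analysis of habitual milk consumption, built
around a single lactase-persistence instrument. It is aimed at genetic
epidemiologists who want to run, audit or extend this style of analysis
without access to the original, access-controlled cohorts: every stage is
driven by a synthetic-biobank generator with the same statistical
structure, and the published summary estimates are reproduced as worked
examples.

## The analysis

A SNP upstream of *LCT* (rs4988235) governs lactase persistence and is a
strong instrument for milk intake: each milk-increasing allele raises
consumption by β̂ = 17.1 g/day (95% CI 10.6–23.6) and explains ≈2% of the
phenotypic variance. The pipeline has four stages:

1. **Genetic score.** Per-person score `s_i = d_i · β̂ / 50`, so a
   regression coefficient on `s` reads as log-odds per 50 g/day of
   genetically predicted milk intake. Instrument strength is summarised
   by `R²` and the one-regressor `F = R²(n−2)/(1−R²)`.
2. **Phecode phenotypes.** ICD-9/ICD-10 diagnosis records are mapped to
   phecodes (a person is a case on ≥1 mapped record); non-cases who are
   cases of a neighbouring phecode inside the phecode's exclusion range
   are removed from its control pool; phenotypes with < 200 cases are
   dropped.
3. **PheWAS scan.** For each retained phecode, a maximum-likelihood
   logistic regression of case status on the score, adjusted for age,
   sex, BMI, assessment center and ten genetic principal components, with
   a no-BMI sensitivity scan and BMI < 25 / ≥ 25 kg/m² stratification.
   Two-sided Wald p-values are corrected across the whole scan with
   Benjamini–Hochberg FDR.
4. **Two-sample MR.** For outcome summary statistics from an independent
   sample, the Wald ratio `β_MR = β_outcome / β_exposure` with the
   delta-method standard error (first-order by default,
   `se = se_out/|β_exp|`), rescaled to 50 g/day and expressed as
   `OR = exp(β_MR)` with a Wald CI.

Because the real data (UK Biobank, FinnGen, consortium GWAS) are
access-controlled, `milkmr.synthetic_biobank` generates cohorts with one
biallelic SNP under Hardy–Weinberg equilibrium, an exposure calibrated so
the instrument explains a target R², and binary phenotypes drawn from
logistic models with a chosen causal log-OR per 50 g/day — so every
downstream estimate has a known generative truth to recover.

## Worked example

Converting a published per-50 g/day estimate (cataract: β = −0.120,
SE = 0.029) to an odds ratio:

```python
>>> from milkmr import to_or_ci
>>> est = to_or_ci(-0.120, 0.029)
>>> print(f"OR {est.or_:.2f} ({est.ci_low:.2f}-{est.ci_high:.2f}), p={est.p:.2e}")
OR 0.89 (0.84-0.94), p=3.50e-05
```

i.e. a 50 g/day higher genetically predicted milk intake is associated
with 11% lower odds of cataract. The full pipeline on the default
synthetic study (`configs/default.yaml`, 60,000 people, ten phecode
outcomes):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_phewas_scan.py
python analysis/03_two_sample_mr.py
python analysis/04_report.py
```

prints, for the simulation step,

```
simulated cohort: n=60000, seed=42
instrument R^2 = 0.0195 (target 0.02), F = 1193.9
```

(the realised instrument R² matches its 2% calibration target) and, for
the scan, an association table such as

```
scanned 9 phenotypes with >= 200 cases; 1 significant at FDR 0.05
  366 Cataract  OR 0.72 (0.62-0.82) p=1.76e-06 q=0.000
```

where the asthma phenotype (≈175 cases at this cohort size) has been
removed by the 200-case filter. The same stages are available as a CLI
(`milkmr simulate|phewas|mr|report|all`) for user-supplied TSV inputs;
`milkmr mr --ratios <tsv>` converts a table of per-50 g/day (beta, se)
rows straight to ORs.

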