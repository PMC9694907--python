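# Default synthetic-biobank study: one lactase-persistence-style instrument
# (17.1 g/day per allele, ~2% of exposure variance, effect-allele frequency
# 0.70) and ten phecode outcomes with plausible prevalences.  Causal
# log-ORs (per 50 g/day of true milk intake) echo the magnitudes seen in
# published milk MR-PheWAS hits; asthma is given a prevalence low enough
# that it falls under the 200-case filter at the default cohort size,
# exercising the minimum-case rule.
cohort:
  n_individuals: 60000
  seed: 42
  effect_allele_freq: 0.70
  per_allele_effect: 17.1
  target_r2: 0.02
  exposure_mean: 200.0
  bmi_exposure_effect: 0.0
  outcomes:
    - phecode: "366"
      baseline_prevalence: 0.115
      log_or_per_50g: -0.12
      icd_codes: [["H25.1", "ICD10"], ["H26.9", "ICD10"], ["3669", "ICD9"]]
    - phecode: "250.2"
      baseline_prevalence: 0.085
      log_or_per_50g: -0.13
      covariate_log_ors: {bmi: 0.10}
      icd_codes: [["E11.9", "ICD10"], ["25000", "ICD9"]]
    - phecode: "250"
      baseline_prevalence: 0.012
      log_or_per_50g: -0.13
      icd_codes: [["E13.9", "ICD10"], ["2509", "ICD9"]]
    - phecode: "272"
      baseline_prevalence: 0.16
      log_or_per_50g: -0.09
      icd_codes: [["E78.9", "ICD10"], ["E78.5", "ICD10"], ["2724", "ICD9"]]
    - phecode: "272.1"
      baseline_prevalence: 0.155
      log_or_per_50g: -0.09
      icd_codes: [["E78.1", "ICD10"], ["2721", "ICD9"]]
    - phecode: "272.11"
      baseline_prevalence: 0.145
      log_or_per_50g: -0.09
      icd_codes: [["E78.0", "ICD10"], ["E78.00", "ICD10"], ["2720", "ICD9"]]
    - phecode: "362.29"
      baseline_prevalence: 0.022
      log_or_per_50g: -0.23
      icd_codes: [["H35.30", "ICD10"], ["36250", "ICD9"]]
    - phecode: "565.1"
      baseline_prevalence: 0.038
      log_or_per_50g: -0.16
      icd_codes: [["K62.0", "ICD10"], ["K62.1", "ICD10"], ["5690", "ICD9"]]
    - phecode: "401"
      baseline_prevalence: 0.26
      log_or_per_50g: 0.0
      icd_codes: [["I10", "ICD10"], ["4019", "ICD9"]]
    - phecode: "495"
      baseline_prevalence: 0.0028
      log_or_per_50g: 0.0
      icd_codes: [["J45.9", "ICD10"], ["J45.0", "ICD10"], ["49390", "ICD9"]]

instrument:
  snp: rs4988235
  effect_allele: T
  other_allele: C
  per_allele_effect_g: 17.1
  ci_low: 10.6
  ci_high: 23.6

scan:
  min_cases: 200
  fdr_level: 0.05
  include_bmi: true
  bmi_cut: 25.0

mr:
  unit_g: 50.0
  method: first_order
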