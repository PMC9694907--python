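"""Generative model: HWE, exposure calibration, outcomes, ICD emission."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from milkmr import (
    AnalysisError,
    CohortConfig,
    OutcomeSpec,
    ValidationError,
    emit_icd_records,
    generate_exposure,
    generate_genotypes,
    generate_outcomes,
    generate_summary_stats,
    map_records,
    mr_pipeline,
    simulate_cohort,
    variance_explained,
    weighted_score,
)
from milkmr.synthetic_biobank import generate_covariates


class TestGenotypes:
    def test_hardy_weinberg_fractions(self):
        n, f = 100_000, 0.7
        g = generate_genotypes(n, f, seed=1)
        expected = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        observed = np.bincount(g, minlength=3) / n
        mc_se = np.sqrt(expected * (1 - expected) / n)
        assert (np.abs(observed - expected) < 4 * mc_se).all()

    @pytest.mark.parametrize("freq, value", [(0.0, 0), (1.0, 2)])
    def test_degenerate_frequencies(self, freq, value):
        assert (generate_genotypes(100, freq, seed=0) == value).all()

    def test_invalid_frequency_rejected(self):
        for bad in (-0.1, 1.5, np.nan):
            with pytest.raises(ValidationError):
                generate_genotypes(10, bad, seed=0)

    def test_reproducible(self):
        assert (generate_genotypes(1000, 0.7, seed=9) == generate_genotypes(1000, 0.7, seed=9)).all()


class TestExposure:
    def test_r2_calibration_hits_target(self):
        config = CohortConfig(n_individuals=100_000, seed=2)
        g = generate_genotypes(config.n_individuals, config.effect_allele_freq, config.seed)
        x = generate_exposure(g, None, config)
        score = weighted_score(g)
        assert 0.015 <= variance_explained(score, x) <= 0.025

    def test_null_instrument_needs_explicit_noise(self):
        config = CohortConfig(n_individuals=100_000, seed=2, per_allele_effect=0.0, noise_sd=77.6)
        g = generate_genotypes(config.n_individuals, config.effect_allele_freq, config.seed)
        x = generate_exposure(g, None, config)
        assert variance_explained(g.astype(float), x) < 1e-3
        with pytest.raises(ValidationError):
            generate_exposure(g, None, CohortConfig(n_individuals=10, per_allele_effect=0.0))

    def test_monomorphic_instrument_rejected(self):
        config = CohortConfig(n_individuals=100, seed=0)
        with pytest.raises(ValidationError):
            generate_exposure(np.zeros(100, dtype=np.int8), None, config)

    def test_mean_matches_truncated_normal_expectation(self):
        """Oracle: the floor at 0 g/day makes the mean the HWE-weighted
        expectation of max(0, N(mu_d, sigma)) per dosage class."""
        f, eff, mean = 0.7, 17.1, 100.0
        config = CohortConfig(n_individuals=200_000, seed=4, exposure_mean=mean)
        g = generate_genotypes(config.n_individuals, f, config.seed)
        x = generate_exposure(g, None, config)
        sigma = eff * np.sqrt(2 * f * (1 - f) * (1 - 0.02) / 0.02)
        weights = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        mus = mean + eff * np.arange(3)
        # E[max(0, N(mu, s))] = mu * Phi(mu/s) + s * phi(mu/s)
        class_means = mus * stats.norm.cdf(mus / sigma) + sigma * stats.norm.pdf(mus / sigma)
        expected = float(weights @ class_means)
        mc_se = sigma / np.sqrt(config.n_individuals)
        assert abs(x.mean() - expected) < 3 * mc_se

    def test_never_negative(self):
        config = CohortConfig(n_individuals=50_000, seed=5, exposure_mean=50.0)
        g = generate_genotypes(config.n_individuals, 0.7, config.seed)
        assert generate_exposure(g, None, config).min() >= 0.0


class TestOutcomes:
    def test_null_marginal_prevalence(self):
        n, prev = 100_000, 0.05
        spec = OutcomeSpec("366", prev, 0.0, icd_codes=(("H25.1", "ICD10"),))
        x = np.full(n, 200.0)
        pheno = generate_outcomes(x, None, [spec], seed=6)
        mc_se = np.sqrt(prev * (1 - prev) / n)
        assert abs(pheno["366"].mean() - prev) < 3 * mc_se

    def test_prevalence_bounds_enforced(self):
        with pytest.raises(ValidationError):
            OutcomeSpec("366", 0.0, icd_codes=(("H25.1", "ICD10"),))
        with pytest.raises(ValidationError):
            OutcomeSpec("366", 1.0, icd_codes=(("H25.1", "ICD10"),))

    def test_outcome_substreams_do_not_perturb_each_other(self, mini_map):
        spec_a = OutcomeSpec("366", 0.1, -0.1, icd_codes=(("H25.1", "ICD10"),))
        spec_b = OutcomeSpec("401", 0.2, 0.0, icd_codes=(("I10", "ICD10"),))
        one = CohortConfig(n_individuals=5000, seed=8, outcome_specs=(spec_a,))
        two = CohortConfig(n_individuals=5000, seed=8, outcome_specs=(spec_b, spec_a))
        sim1, sim2 = simulate_cohort(one, mini_map), simulate_cohort(two, mini_map)
        assert (sim1.cohort["dosage"] == sim2.cohort["dosage"]).all()
        assert (sim1.cohort["exposure"] == sim2.cohort["exposure"]).all()
        assert (sim1.cohort["case_366"] == sim2.cohort["case_366"]).all()

    def test_null_effect_ci_covers_one(self, mini_map):
        """With theta=0 the scan's 95% CI covers OR=1 in >=90% of replicates."""
        from milkmr.phewas_scan import fit_logistic

        spec = OutcomeSpec("401", 0.12, 0.0, icd_codes=(("I10", "ICD10"),))
        reps, covered = 100, 0
        for seed in range(reps):
            config = CohortConfig(n_individuals=6000, seed=seed, outcome_specs=(spec,))
            sim = simulate_cohort(config)
            fit = fit_logistic(
                sim.cohort["case_401"].to_numpy(),
                weighted_score(sim.cohort["dosage"].to_numpy()),
            )
            covered += abs(fit.beta) < 1.959963985 * fit.se
        assert covered >= int(0.9 * reps)


class TestIcdEmission:
    def test_round_trip_is_exact(self, mini_map, small_cohort):
        ind = map_records(small_cohort.records, mini_map)
        cases = ind.reindex(small_cohort.cohort.index, fill_value=False)["366"]
        assert (cases.to_numpy() == (small_cohort.cohort["case_366"] == 1).to_numpy()).all()

    def test_exact_case_count_round_trip(self, mini_map):
        pheno = pd.DataFrame({"366": np.repeat([1, 0], [500, 300]).astype(np.int8)})
        records = emit_icd_records(pheno, mini_map, seed=10)
        ind = map_records(records, mini_map)
        assert int(ind["366"].sum()) == 500

    def test_zero_cases_empty_table(self, mini_map):
        pheno = pd.DataFrame({"366": np.zeros(100, dtype=np.int8)})
        assert len(emit_icd_records(pheno, mini_map, seed=0)) == 0

    def test_both_vocabularies_emitted(self, mini_map):
        spec = OutcomeSpec("366", 0.5, 0.0, icd_codes=(("H25.1", "ICD10"), ("3669", "ICD9")))
        pheno = pd.DataFrame({"366": np.ones(500, dtype=np.int8)})
        records = emit_icd_records(pheno, mini_map, seed=1, specs=[spec])
        assert set(records["vocabulary"]) == {"ICD9", "ICD10"}

    def test_unmapped_spec_code_rejected_by_name(self, mini_map):
        spec = OutcomeSpec("366", 0.5, 0.0, icd_codes=(("Z99.9", "ICD10"),))
        pheno = pd.DataFrame({"366": np.ones(5, dtype=np.int8)})
        with pytest.raises(ValidationError, match="Z99.9"):
            emit_icd_records(pheno, mini_map, seed=1, specs=[spec])


class TestSummaryStats:
    def test_exposure_beta_recovers_generative_value(self, small_cohort):
        exp_stat, _ = generate_summary_stats(small_cohort.cohort, "366")
        assert abs(exp_stat.beta - 17.1) < 3 * exp_stat.se

    def test_wald_recovers_theta_within_sampling_error(self, small_cohort):
        exp_stat, out_stat = generate_summary_stats(small_cohort.cohort, "366")
        est = mr_pipeline(exp_stat, out_stat, unit_g=50.0)
        assert abs(est.beta_mr - (-0.12)) < 3.5 * est.se_mr

    def test_zero_cases_rejected(self, mini_map):
        spec = OutcomeSpec("366", 0.1, 0.0, icd_codes=(("H25.1", "ICD10"),))
        config = CohortConfig(n_individuals=500, seed=3, outcome_specs=(spec,))
        sim = simulate_cohort(config)
        cohort = sim.cohort.copy()
        cohort["case_366"] = 0
        with pytest.raises(AnalysisError):
            generate_summary_stats(cohort, "366")


def test_full_simulation_reproducible(mini_map, cataract_spec):
    config = CohortConfig(n_individuals=3000, seed=17, outcome_specs=(cataract_spec,))
    a, b = simulate_cohort(config, mini_map), simulate_cohort(config, mini_map)
    pd.testing.assert_frame_equal(a.cohort, b.cohort)
    pd.testing.assert_frame_equal(a.records, b.records)


def test_covariate_distributions(mini_map):
    config = CohortConfig(n_individuals=50_000, seed=21)
    cov = generate_covariates(config)
    assert cov["age"].between(40, 69).all()
    assert abs(cov["sex"].mean() - 0.537) < 0.01
    assert abs(cov["bmi"].mean() - 27) < 0.1
    assert cov["center"].nunique() == 5
    assert abs(cov["pc1"].std() - 1) < 0.02
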