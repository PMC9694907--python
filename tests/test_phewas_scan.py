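"""Logistic scan, BH-FDR, BMI sensitivity and stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from milkmr import (
    AnalysisError,
    CohortConfig,
    OutcomeSpec,
    ScanConfig,
    ValidationError,
    bh_fdr,
    build_phenotype_matrix,
    fit_logistic,
    map_records,
    run_phewas,
    simulate_cohort,
    stratified_scan,
    weighted_score,
)
from milkmr.phewas_scan import DEFAULT_COVARIATES


def bh_brute_force(p):
    """Independent O(m^2) transcription of the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for i, idx in enumerate(order, start=1):
        q[idx] = min(min(p[order[j - 1]] * m / j for j in range(i, m + 1)), 1.0)
    return q


class TestBhFdr:
    def test_worked_example(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.005, 0.025, 1 / 30, 0.0375, 0.04], rtol=1e-12)

    def test_single_p_and_cap(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(ValidationError):
                bh_fdr(bad)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=60))
    def test_matches_brute_force_and_statsmodels(self, p):
        q = bh_fdr(p)
        np.testing.assert_array_equal(q, bh_brute_force(p))
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, rtol=1e-12, atol=0)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=60))
    def test_monotone_and_dominating(self, p):
        q = bh_fdr(p)
        assert (q >= np.asarray(p) * (1 - 1e-12)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestFitLogistic:
    def test_recovers_generative_effect(self, small_cohort):
        cohort = small_cohort.cohort
        fit = fit_logistic(
            cohort["case_366"].to_numpy(),
            weighted_score(cohort["dosage"].to_numpy()),
            cohort.reset_index(drop=True),
            ("age", "sex", "bmi"),
        )
        assert fit.converged
        assert abs(fit.beta - (-0.12)) < 3.5 * fit.se

    def test_constant_score_rejected_by_name(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 500)
        with pytest.raises(ValidationError, match="score"):
            fit_logistic(y, np.full(500, 0.684))

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(1)
        n = 500
        cov = pd.DataFrame({"age": rng.uniform(40, 69, n)})
        cov["age_copy"] = cov["age"]
        with pytest.raises(ValidationError, match="age"):
            fit_logistic(
                rng.integers(0, 2, n),
                rng.choice([0, 0.342, 0.684], n),
                cov,
                ("age", "age_copy"),
            )

    def test_separation_flagged_not_raised(self):
        score = np.repeat([0.0, 0.684], 100)
        y = (score > 0).astype(float)  # perfectly separated
        fit = fit_logistic(y, score)
        assert not fit.converged
        assert fit.note != ""

    def test_needs_both_classes(self):
        with pytest.raises(AnalysisError):
            fit_logistic(np.ones(50), np.linspace(0, 0.684, 50))


def _crafted_matrix(mini_map, counts, n):
    """Phenotype matrix with exact case counts per phecode."""
    rows = []
    for ph, k in counts.items():
        code = mini_map.codes_for(ph).iloc[0]
        rows += [(p, code["icd_code"], code["vocabulary"]) for p in range(k)]
    rec = pd.DataFrame(rows, columns=["person_id", "code", "vocabulary"])
    return build_phenotype_matrix(map_records(rec, mini_map), mini_map, range(n))


class TestRunPhewas:
    def _inputs(self, mini_map, n=2500, seed=0):
        rng = np.random.default_rng(seed)
        score = weighted_score(rng.binomial(2, 0.7, n))
        cov = pd.DataFrame({"age": rng.uniform(40, 69, n), "sex": rng.integers(0, 2, n)})
        return score, cov

    def test_min_case_filter_shapes_output(self, mini_map):
        counts = {ph: 400 for ph in ["366", "401", "495", "250", "272", "272.1", "565.1", "362.29"]}
        counts["250.2"] = 150
        counts["272.11"] = 199
        mat = _crafted_matrix(mini_map, counts, 2500)
        score, cov = self._inputs(mini_map)
        res = run_phewas(mat, score, cov, ScanConfig(covariates=("age", "sex"), min_cases=200))
        assert len(res) == 8
        assert not {"250.2", "272.11"} & set(res["phecode"])

    def test_deterministic_and_sorted(self, mini_map):
        mat = _crafted_matrix(mini_map, {"366": 300, "401": 300}, 1500)
        score, cov = self._inputs(mini_map, n=1500)
        config = ScanConfig(covariates=("age", "sex"), min_cases=200)
        a = run_phewas(mat, score, cov, config)
        b = run_phewas(mat, score, cov, config)
        pd.testing.assert_frame_equal(a, b)
        assert list(a["phecode"]) == sorted(a["phecode"], key=str)

    def test_empty_scan_rejected(self, mini_map):
        mat = _crafted_matrix(mini_map, {"366": 10}, 100)
        score, cov = self._inputs(mini_map, n=100)
        with pytest.raises(AnalysisError):
            run_phewas(mat, score, cov, ScanConfig(covariates=("age", "sex"), min_cases=200))

    def test_q_dominates_p_and_flags_match(self, mini_map):
        counts = {ph: 300 for ph in ["366", "401", "250", "272"]}
        mat = _crafted_matrix(mini_map, counts, 2000)
        score, cov = self._inputs(mini_map, n=2000, seed=4)
        res = run_phewas(mat, score, cov, ScanConfig(covariates=("age", "sex"), min_cases=200))
        assert (res["q"] >= res["p"] - 1e-15).all()
        assert (res["significant"] == (res["q"] <= 0.05)).all()


class TestBmiSensitivity:
    def test_mediated_effect_shrinks_under_bmi_adjustment(self, mini_map):
        """BMI built as a mediator (exposure raises BMI, BMI raises risk):
        the unadjusted scan shows a positive genetic association that the
        BMI-adjusted scan removes, matching the generative direction."""
        spec = OutcomeSpec(
            "401", 0.15, 0.0, covariate_log_ors={"bmi": 0.15}, icd_codes=(("I10", "ICD10"),)
        )
        config = CohortConfig(
            n_individuals=40_000, seed=12, bmi_exposure_effect=0.05, outcome_specs=(spec,)
        )
        sim = simulate_cohort(config, mini_map)
        cohort = sim.cohort
        score = weighted_score(cohort["dosage"].to_numpy())
        cov = cohort.reset_index(drop=True)
        names = ("age", "sex", "bmi")
        adj = fit_logistic(cohort["case_401"].to_numpy(), score, cov, names, include_bmi=True)
        unadj = fit_logistic(cohort["case_401"].to_numpy(), score, cov, names, include_bmi=False)
        assert unadj.beta > 2 * unadj.se  # mediated path visible
        assert unadj.beta > adj.beta + 0.1  # sign(0.05 * 0.15) > 0
        assert abs(adj.beta) < 4 * adj.se  # direct effect is null


class TestStratifiedScan:
    def test_partition_and_within_stratum_filter(self, mini_map):
        n = 3000
        rng = np.random.default_rng(9)
        score = weighted_score(rng.binomial(2, 0.7, n))
        bmi = np.where(np.arange(n) < 1000, 22.0, 28.0)  # 1000 lean / 2000 overweight
        cov = pd.DataFrame({"age": rng.uniform(40, 69, n), "sex": rng.integers(0, 2, n), "bmi": bmi})
        # 366: 150 cases among the lean, 400 among the overweight.
        rows = [(p, "H251", "ICD10") for p in range(150)]
        rows += [(p, "H251", "ICD10") for p in range(1000, 1400)]
        rows += [(p, "I10", "ICD10") for p in range(0, 3000, 3)]  # plenty in both strata
        rec = pd.DataFrame(rows, columns=["person_id", "code", "vocabulary"])
        mat = build_phenotype_matrix(map_records(rec, mini_map), mini_map, range(n))
        config = ScanConfig(covariates=("age", "sex", "bmi"), min_cases=200)
        low, high = stratified_scan(mat, score, cov, config)
        assert "366" not in set(low["phecode"]) and "366" in set(high["phecode"])
        assert set(low["phecode"]) <= {"401"} and "401" in set(high["phecode"])
        n_low = low.loc[low["phecode"] == "401", ["n_case", "n_control"]].sum(axis=1).iloc[0]
        n_high = high.loc[high["phecode"] == "401", ["n_case", "n_control"]].sum(axis=1).iloc[0]
        assert n_low + n_high == n

    def test_homogeneous_effect_agrees_across_strata(self, mini_map):
        """With one generative theta, stratum estimates agree within joint
        95% CIs in >= 90% of replicates."""
        spec = OutcomeSpec("366", 0.2, -0.12, icd_codes=(("H25.1", "ICD10"),))
        agree = 0
        reps = 20
        for seed in range(reps):
            config = CohortConfig(n_individuals=6000, seed=seed, outcome_specs=(spec,))
            sim = simulate_cohort(config, mini_map)
            cohort = sim.cohort
            score = weighted_score(cohort["dosage"].to_numpy())
            lean = cohort["bmi"].to_numpy() < 25.0
            fits = []
            for mask in (lean, ~lean):
                fits.append(
                    fit_logistic(
                        cohort["case_366"].to_numpy()[mask],
                        score[mask],
                        cohort.reset_index(drop=True).loc[mask].reset_index(drop=True),
                        ("age", "sex"),
                    )
                )
            gap = abs(fits[0].beta - fits[1].beta)
            agree += gap < 1.959963985 * np.hypot(fits[0].se, fits[1].se)
        assert agree >= int(0.9 * reps)

    def test_empty_stratum_rejected(self, mini_map):
        mat = _crafted_matrix(mini_map, {"366": 300}, 1000)
        rng = np.random.default_rng(0)
        score = weighted_score(rng.binomial(2, 0.7, 1000))
        cov = pd.DataFrame({"age": rng.uniform(40, 69, 1000), "sex": rng.integers(0, 2, 1000),
                            "bmi": np.full(1000, 30.0)})
        with pytest.raises(AnalysisError):
            stratified_scan(mat, score, cov, ScanConfig(covariates=("age", "sex", "bmi"), min_cases=100))
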