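"""Cohort statistics: closed-form oracles, identities and recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from interprox.stats import (
    PUBLISHED_MODEL,
    AnalysisConfig,
    SeparationError,
    corr_pvalue_from_r,
    correlation,
    describe_normality,
    fit_logistic,
    odds_ratio,
    pca_with_screening,
    published_risk_score,
    run_full_analysis,
    ttest_from_summary,
    two_sample_ttest,
)
from interprox.synthetic import (
    FEATURE_COLUMNS,
    IMPACTION_GROUP,
    NONIMPACTION_GROUP,
    generate_cohort,
)

MODEL_FEATURES = [k for k in PUBLISHED_MODEL if k != "intercept"]


class TestNormality:
    def test_normal_samples_rarely_rejected(self):
        rng = np.random.default_rng(0)
        keep = sum(describe_normality(rng.normal(size=500)).sw_p > 0.05
                   for _ in range(60))
        assert keep >= 0.90 * 60  # Shapiro-Wilk type-I error is 5%

    def test_exponential_samples_nearly_always_rejected(self):
        rng = np.random.default_rng(1)
        reject = sum(describe_normality(rng.exponential(size=500)).sw_p < 0.05
                     for _ in range(40))
        assert reject == 40

    def test_moments_of_a_symmetric_sample(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=4000)
        res = describe_normality(x)
        assert res.skewness == pytest.approx(0.0, abs=0.15)
        assert res.excess_kurtosis == pytest.approx(0.0, abs=0.3)
        assert res.n == 4000

    def test_ks_variants_differ_in_p_not_d(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        lil = describe_normality(x, ks_variant="lilliefors")
        naive = describe_normality(x, ks_variant="fitted_normal")
        assert lil.ks_D == pytest.approx(naive.ks_D, abs=1e-12)
        # the naive variant ignores parameter estimation: anti-conservative D
        # distribution, hence a larger p for the same statistic
        assert naive.ks_p >= lil.ks_p

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            describe_normality(np.ones(100))
        with pytest.raises(ValueError):
            describe_normality(np.arange(5))


class TestTTest:
    def test_identical_groups_give_t0_p1(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = two_sample_ttest(x, x.copy())
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_raw_and_summary_variants_agree(self, rng):
        x, y = rng.normal(0, 1, 40), rng.normal(0.4, 1.3, 55)
        for variant in ("welch", "student"):
            raw = two_sample_ttest(x, y, variant)
            summ = ttest_from_summary(
                x.mean(), x.std(ddof=1), x.size,
                y.mean(), y.std(ddof=1), y.size, variant)
            assert raw.t == pytest.approx(summ.t, abs=1e-12)
            assert raw.p == pytest.approx(summ.p, abs=1e-12)

    def test_tongue_angle_row_not_significant_at_50_per_group(self):
        m1, s1 = NONIMPACTION_GROUP.moments["tongue_angle_deg"]
        m2, s2 = IMPACTION_GROUP.moments["tongue_angle_deg"]
        res = ttest_from_summary(m1, s1, 50, m2, s2, 50)
        assert 0.05 < res.p < 0.15  # printed two-sided p is 0.087

    def test_welch_matches_scipy_on_raw_data(self, rng):
        x, y = rng.normal(size=30), rng.normal(0.5, 2.0, size=45)
        res = two_sample_ttest(x, y, "welch")
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(float(ref.statistic), abs=1e-12)
        assert res.df == pytest.approx(float(ref.df), rel=1e-9)

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        reps, n = 2000, 50
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        p = sps.ttest_ind(x, y, axis=1, equal_var=False).pvalue
        rate = float((p < 0.05).mean())
        assert rate == pytest.approx(0.05, abs=0.015)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            ttest_from_summary(1.0, 0.0, 10, 2.0, 0.0, 10)
        with pytest.raises(ValueError):
            two_sample_ttest([1, 2], [3, 4], variant="bayes")


class TestCorrelation:
    @pytest.mark.parametrize("r,printed_p", [
        (0.317, 0.025), (0.297, 0.036), (0.171, 0.236),
        (0.077, 0.594), (0.078, 0.592), (0.036, 0.803),
    ])
    def test_printed_coefficients_reproduce_printed_p(self, r, printed_p):
        assert corr_pvalue_from_r(r, 50) == pytest.approx(printed_p, abs=0.003)

    def test_zero_correlation_p_is_one(self):
        assert corr_pvalue_from_r(0.0, 50) == pytest.approx(1.0)

    def test_perfect_correlation_p_is_zero(self):
        assert corr_pvalue_from_r(1.0, 50) == 0.0
        assert corr_pvalue_from_r(-1.0, 10) == 0.0

    def test_spearman_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=80)
        y = x + rng.normal(0, 0.5, 80)
        a = correlation(x, y, "spearman")
        b = correlation(np.exp(x), y, "spearman")
        assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_pearson_matches_scipy(self, rng):
        x, y = rng.normal(size=60), rng.normal(size=60)
        res = correlation(x, y, "pearson")
        assert res.r == pytest.approx(float(sps.pearsonr(x, y).statistic))

    @given(hst.floats(-0.99, 0.99), hst.integers(5, 500))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_pvalue_in_unit_interval_and_symmetric(self, r, n):
        p = corr_pvalue_from_r(r, n)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(corr_pvalue_from_r(-r, n), abs=1e-12)


class TestPCA:
    def _correlated_table(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=n)
        data = {
            "a": base + rng.normal(0, 0.4, n),
            "b": base + rng.normal(0, 0.4, n),
            "c": -base + rng.normal(0, 0.4, n),
            "d": base + rng.normal(0, 0.5, n),
            "noise": rng.normal(size=n),
        }
        return pd.DataFrame(data)

    def test_communality_identity_and_eigenvalue_sum(self):
        table = self._correlated_table()
        for rnd in pca_with_screening(table):
            np.testing.assert_allclose(
                rnd.communalities, (rnd.loadings ** 2).sum(axis=1), atol=1e-12)
            assert rnd.eigenvalues.sum() == pytest.approx(len(rnd.items),
                                                          abs=1e-10)

    def test_pure_noise_item_dropped_first(self):
        rounds = pca_with_screening(self._correlated_table())
        assert rounds[0].dropped_item == "noise"
        assert all(rounds[-1].communalities >= 0.4)

    def test_two_perfectly_correlated_items(self, rng):
        x = rng.normal(size=100)
        table = pd.DataFrame({"a": x, "b": 2 * x + 1})
        rnd = pca_with_screening(table)[0]
        assert rnd.eigenvalues[0] == pytest.approx(2.0, abs=1e-10)
        np.testing.assert_allclose(rnd.communalities, 1.0, atol=1e-10)

    def test_loading_sign_convention(self):
        rounds = pca_with_screening(self._correlated_table(seed=3))
        for rnd in rounds:
            for k in range(rnd.n_retained):
                j = int(np.argmax(np.abs(rnd.loadings[:, k])))
                assert rnd.loadings[j, k] > 0

    def test_degenerate_tables_rejected(self, rng):
        const = pd.DataFrame({"a": np.ones(50), "b": rng.normal(size=50)})
        with pytest.raises(ValueError):
            pca_with_screening(const)
        tiny = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            pca_with_screening(tiny)


class TestLogistic:
    def _simulated(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        eta = 0.5 + 1.2 * X[:, 0] - 0.8 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return X, y

    def test_matches_direct_likelihood_maximization(self):
        X, y = self._simulated(n=100, seed=1)
        model = fit_logistic(X, y)

        from scipy.optimize import minimize

        def nll(beta):
            eta = beta[0] + X @ beta[1:]
            return np.sum(np.log1p(np.exp(eta)) - y * eta)

        ref = minimize(nll, np.zeros(3), method="BFGS", tol=1e-12)
        np.testing.assert_allclose(model.coef, ref.x, atol=1e-6)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        X, y = self._simulated(seed=2)
        model = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(model.coef, ref.params, atol=1e-8)
        np.testing.assert_allclose(model.se, ref.bse, rtol=1e-6)

    def test_rescaling_a_feature_rescales_its_coefficient(self):
        X, y = self._simulated(seed=3)
        a = fit_logistic(X, y)
        X2 = X.copy()
        X2[:, 0] *= 2.0
        b = fit_logistic(X2, y)
        assert b.coef[1] == pytest.approx(a.coef[1] / 2.0, rel=1e-6)
        assert b.coef[2] == pytest.approx(a.coef[2], rel=1e-6)

    def test_constant_feature_rejected(self):
        X, y = self._simulated(seed=4)
        X[:, 1] = 3.0
        with pytest.raises(ValueError, match="singular|constant"):
            fit_logistic(X, y)

    def test_separation_detected(self):
        x = np.linspace(-1, 1, 60)
        y = (x > 0).astype(int)
        with pytest.raises(SeparationError):
            fit_logistic(x[:, None], y)

    def test_invalid_outcomes_rejected(self):
        X, _ = self._simulated(seed=5)
        with pytest.raises(ValueError):
            fit_logistic(X, np.full(len(X), 2))
        with pytest.raises(ValueError):
            fit_logistic(X, np.zeros(len(X)))

    def test_wald_and_or_identities(self):
        X, y = self._simulated(seed=6)
        model = fit_logistic(X, y)
        np.testing.assert_allclose(model.wald_chi2,
                                   (model.coef / model.se) ** 2, rtol=1e-12)
        np.testing.assert_allclose(model.odds_ratios, np.exp(model.coef),
                                   rtol=1e-12)
        upper = np.log(model.ci_upper / model.odds_ratios)
        lower = np.log(model.ci_lower / model.odds_ratios)
        np.testing.assert_allclose(upper, -lower, atol=1e-12)


class TestOddsRatio:
    @pytest.mark.parametrize("beta,se,printed_or", [
        (-0.071, 0.031, 0.931),
        (-0.089, 0.022, 0.915),
    ])
    def test_printed_negative_coefficients(self, beta, se, printed_or):
        value, (lo, hi) = odds_ratio(beta, se)
        assert value == pytest.approx(printed_or, abs=5e-4)
        assert lo < value < hi

    def test_zero_beta_gives_unit_or_with_symmetric_ci(self):
        value, (lo, hi) = odds_ratio(0.0, 0.2)
        assert value == 1.0
        assert math.log(hi) == pytest.approx(-math.log(lo), abs=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(0.5, 0.0)


class TestPublishedScore:
    def test_all_zero_features(self):
        record = {f: 0.0 for f in MODEL_FEATURES}
        p = published_risk_score(record)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(19.797)), rel=1e-12)

    def test_reference_feature_values(self):
        record = {"adjacent_line_length_mm": 3.52,
                  "adjacent_surface_area_mm2": 6.21,
                  "buccal_angle_deg": 54.15,
                  "occlusal_angle_deg": 89.26}
        p = published_risk_score(record)
        logit = math.log(p / (1 - p))
        assert logit == pytest.approx(-7.367, abs=5e-3)
        assert p == pytest.approx(6.3e-4, rel=0.02)

    def test_dataframe_input_vectorizes(self):
        frame = pd.DataFrame([{f: 1.0 for f in MODEL_FEATURES}] * 3)
        p = published_risk_score(frame)
        assert p.shape == (3,)
        assert np.all(p == p[0])

    def test_missing_feature_rejected(self):
        with pytest.raises(KeyError):
            published_risk_score({"adjacent_line_length_mm": 3.0})

    @given(hst.floats(1.0, 6.0), hst.floats(4.0, 10.0),
           hst.floats(20.0, 90.0), hst.floats(20.0, 130.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_risk_monotone_in_each_feature(self, length, area, buccal,
                                           occlusal):
        record = {"adjacent_line_length_mm": length,
                  "adjacent_surface_area_mm2": area,
                  "buccal_angle_deg": buccal,
                  "occlusal_angle_deg": occlusal}
        p0 = published_risk_score(record)
        up = dict(record, adjacent_line_length_mm=length + 0.1)
        assert published_risk_score(up) > p0
        steeper = dict(record, occlusal_angle_deg=occlusal + 1.0)
        assert published_risk_score(steeper) < p0


class TestFullAnalysis:
    def test_headline_significance_pattern(self):
        """Simulated study cohort: line length, area and occlusal angle are
        strongly significant; at ~50 per group the tongue and buccal angles
        are usually not."""
        cohort = generate_cohort(seed=11, n_per_group=250)
        report = run_full_analysis(cohort)
        sig = set(report.significant_features())
        assert {"adjacent_line_length_mm", "adjacent_surface_area_mm2",
                "occlusal_angle_deg"} <= sig
        small = generate_cohort(seed=12, n_per_group=50)
        rep_small = run_full_analysis(small)
        comp = rep_small.group_comparison
        assert comp.loc["adjacent_line_length_mm", "p"] < 0.001
        assert comp.loc["occlusal_angle_deg", "p"] < 0.001

    def test_null_cohort_per_feature_rejection_near_alpha(self):
        null_group = NONIMPACTION_GROUP
        rejections = np.zeros(len(FEATURE_COLUMNS))
        reps = 40
        rng = np.random.default_rng(13)
        for _ in range(reps):
            cohort = generate_cohort([null_group, null_group],
                                     seed=int(rng.integers(1 << 31)),
                                     n_per_group=50)
            cohort["outcome"] = np.repeat([0, 1], 50)
            report = run_full_analysis(cohort)
            rejections += (report.group_comparison["p"] < 0.05).to_numpy(float)
        assert np.all(rejections / reps <= 0.2)

    def test_deterministic_given_cohort(self):
        cohort = generate_cohort(seed=14, n_per_group=60)
        a = run_full_analysis(cohort)
        b = run_full_analysis(cohort)
        pd.testing.assert_frame_equal(a.group_comparison, b.group_comparison)
        pd.testing.assert_frame_equal(a.correlations, b.correlations)

    def test_report_written_to_directory(self, tmp_path):
        cohort = generate_cohort(seed=15, n_per_group=60)
        report = run_full_analysis(cohort)
        files = report.to_dir(tmp_path)
        for name in files:
            assert (tmp_path / name).exists()
        assert "report.json" in files

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            run_full_analysis(pd.DataFrame({"outcome": [0, 1]}))
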