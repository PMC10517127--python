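import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from perivasc import (
    InputError,
    duration_subanalysis,
    generate_records,
    group_comparison,
    icc_agreement,
    paired_quadrant_test,
    regression_suite,
)

HAND_MATRIX = np.array([[7.0, 9.0], [5.0, 6.0], [8.0, 8.0], [2.0, 3.0], [6.0, 7.0]])


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.tile(np.array([3.0, 5.0, 9.0, 1.0])[:, None], (1, 3))
        single, average = icc_agreement(x)
        assert single == pytest.approx(1.0)
        assert average == pytest.approx(1.0)

    def test_hand_built_matrix_matches_mean_squares_oracle(self):
        # frozen from the textbook ANOVA decomposition computed by hand:
        # MSR = 10.35, MSC = 2.5, MSE = 0.25 for the 5x2 matrix
        single, average = icc_agreement(HAND_MATRIX)
        assert single == pytest.approx(0.878260869565, abs=1e-9)
        assert average == pytest.approx(0.935185185185, abs=1e-9)

    def test_matches_pingouin_absolute_agreement(self):
        pg = pytest.importorskip("pingouin")
        n, k = HAND_MATRIX.shape
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": list(range(k)) * n,
                "score": HAND_MATRIX.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "subject", "rater", "score").set_index("Type")
        key_1 = "ICC(A,1)" if "ICC(A,1)" in ref.index else "ICC2"
        key_k = "ICC(A,k)" if "ICC(A,k)" in ref.index else "ICC2k"
        single, average = icc_agreement(HAND_MATRIX)
        assert single == pytest.approx(ref.loc[key_1, "ICC"], abs=1e-9)
        assert average == pytest.approx(ref.loc[key_k, "ICC"], abs=1e-9)

    def test_recovers_planted_reliability_in_simulation(self):
        rng = np.random.default_rng(42)
        n, reliability = 200, 0.80
        subject = rng.normal(size=n)
        noise_sd = np.sqrt(1.0 / reliability - 1.0)
        ratings = subject[:, None] + rng.normal(0, noise_sd, (n, 2))
        single, _ = icc_agreement(ratings)
        assert single == pytest.approx(reliability, abs=0.05)

    def test_zero_between_subject_variance_degenerate(self):
        with pytest.warns(UserWarning, match="between-subject"):
            single, average = icc_agreement(np.ones((4, 2)))
        assert single == 0.0 and average == 0.0

    def test_missing_cells_rejected(self):
        x = HAND_MATRIX.copy()
        x[0, 0] = np.nan
        with pytest.raises(InputError):
            icc_agreement(x)


def _three_group_frame(rng, means=(0.0, 0.0, 0.0), n=20, sd=1.0):
    rows = []
    for g, mu in zip(("recurrent", "indolent", "control"), means):
        for v in rng.normal(mu, sd, n):
            rows.append({"group": g, "metric": v})
    return pd.DataFrame(rows)


class TestGroupComparison:
    def test_identical_groups_f_near_zero(self, rng):
        base = rng.normal(size=15)
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b", "c"], 15),
                "metric": np.tile(base, 3),
            }
        )
        gc = group_comparison(df, "metric")
        assert gc.anova_f == pytest.approx(0.0, abs=1e-12)
        assert gc.anova_p == pytest.approx(1.0)

    def test_two_group_anova_equals_pooled_t_squared(self, rng):
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b"], 12),
                "metric": rng.normal(size=24),
            }
        )
        gc = group_comparison(df, "metric")
        t = gc.pairwise[0].t_statistic
        assert gc.anova_f == pytest.approx(t**2, abs=1e-10)

    def test_bonferroni_adjusted_p_bounds(self, rng):
        gc = group_comparison(_three_group_frame(rng, (0.0, 0.3, 0.6)), "metric")
        assert len(gc.pairwise) == 3
        for pc in gc.pairwise:
            assert pc.p_bonferroni >= pc.p_raw
            assert pc.p_bonferroni <= 1.0
            assert pc.p_bonferroni == pytest.approx(min(1.0, 3 * pc.p_raw))

    def test_recovers_planted_ordering(self, rng):
        df = _three_group_frame(rng, means=(1.0, 0.3, 0.0), n=40, sd=0.5)
        gc = group_comparison(df, "metric")
        assert gc.anova_p < 0.05
        assert (
            gc.group_means["recurrent"]
            > gc.group_means["indolent"]
            > gc.group_means["control"] - 0.2
        )

    def test_zero_variance_group_falls_back_to_welch(self, rng):
        df = pd.DataFrame(
            {
                "group": ["a"] * 5 + ["b"] * 5,
                "metric": [2.0] * 5 + list(rng.normal(size=5)),
            }
        )
        gc = group_comparison(df, "metric")
        assert np.isfinite(gc.pairwise[0].p_raw)

    def test_permutation_type_one_error_near_nominal(self):
        """Label-shuffled (null) data rejects at ~5%: calibration check."""
        rng = np.random.default_rng(7)
        n_rep, n = 1000, 30
        a = rng.normal(size=(n_rep, n))
        b = rng.normal(size=(n_rep, n))
        _, p = sps.ttest_ind(a, b, axis=1)
        rate = np.mean(p < 0.05)
        assert 0.03 <= rate <= 0.07


class TestPairedQuadrantTest:
    def test_identical_pairs_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning):
            t, p = paired_quadrant_test(x, x)
        assert t == 0.0 and p == 1.0

    def test_constant_shift_detected(self, rng):
        x = rng.normal(size=30)
        t, p = paired_quadrant_test(x + 1.0, x)
        assert p < 1e-10
        assert t > 0

    def test_planted_shift_recovered_within_two_se(self):
        rng = np.random.default_rng(0)
        n, delta = 60, 0.4
        x = rng.normal(size=n)
        y = x - delta + rng.normal(0, 0.2, n)
        diffs = (x - y)
        se = diffs.std(ddof=1) / np.sqrt(n)
        assert abs(diffs.mean() - delta) < 2 * se
        t, p = paired_quadrant_test(x, y)
        assert p < 0.05


class TestRegressionSuite:
    def test_outcome_equal_to_predictor_gives_beta_one(self, rng):
        v = rng.normal(size=50)
        df = pd.DataFrame({"y": v, "x": v})
        suite = regression_suite(df, outcome="y", predictors=["x"])
        row = suite.univariate[0]
        assert row.standardized_beta == pytest.approx(1.0, abs=1e-10)
        assert row.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_univariate_standardized_beta_equals_pearson_r(self, rng):
        df = pd.DataFrame(
            {"y": rng.normal(size=80), "x": rng.normal(size=80)}
        )
        suite = regression_suite(df, outcome="y", predictors=["x"])
        r, _ = sps.pearsonr(df["x"], df["y"])
        assert suite.univariate[0].standardized_beta == pytest.approx(r, abs=1e-10)

    def test_null_predictor_beta_near_zero_at_large_n(self):
        df = generate_records(5000, seed=3, beta_injections=0.0)
        suite = regression_suite(
            df, predictors=["injections_per_year"]
        )
        assert abs(suite.univariate[0].standardized_beta) < 0.05

    def test_entry_rule_gates_multivariate_model(self):
        df = generate_records(300, seed=5, beta_injections=0.5, n_null_predictors=1)
        suite = regression_suite(
            df, predictors=["injections_per_year", "null_1", "duration_months"]
        )
        assert "injections_per_year" in suite.multivariate_predictors
        by_p = {r.predictor: r.p_value for r in suite.univariate}
        for pred, p in by_p.items():
            assert (pred in suite.multivariate_predictors) == (p < 0.2)

    def test_collinear_design_names_offenders(self, rng):
        x = rng.normal(size=60)
        df = pd.DataFrame({"y": x + rng.normal(0, 0.1, 60), "a": x, "b": 2 * x})
        with pytest.raises(InputError, match="a|b"):
            regression_suite(df, outcome="y", predictors=["a", "b"])

    def test_planted_beta_recovered(self):
        df = generate_records(500, seed=8, beta_injections=0.3)
        suite = regression_suite(df, predictors=["injections_per_year"])
        assert suite.univariate[0].standardized_beta == pytest.approx(0.3, abs=0.1)


class TestDurationSubanalysis:
    def test_all_one_stratum_errors(self):
        df = generate_records(50, seed=2, duration_range=(6.0, 30.0))
        with pytest.raises(InputError, match="stratum"):
            duration_subanalysis(df)

    def test_link_confined_to_early_stratum(self):
        df = generate_records(
            400, seed=4, beta_injections=0.5, beta_injections_late=0.0
        )
        sub = duration_subanalysis(df)
        assert sub.early.p_value < 0.05
        assert sub.early.standardized_beta > 0.3
        assert abs(sub.late.standardized_beta) < 0.2

    def test_stratum_shape_matches_planted_split(self):
        df = generate_records(200, seed=6)
        sub = duration_subanalysis(df, split_months=36.0)
        assert sub.n_early + sub.n_late == 200
        assert sub.n_early == (df["duration_months"] < 36.0).sum()

    def test_tiny_stratum_skips_regression_with_warning(self):
        df = generate_records(40, seed=9, duration_range=(6.0, 35.0))
        df.loc[df.index[:2], "duration_months"] = 40.0
        with pytest.warns(UserWarning, match="skipped"):
            sub = duration_subanalysis(df)
        assert sub.late.standardized_beta is None
        assert sub.n_late == 2
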