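"""Variance decomposition, ICC(A,1) and split-half reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from relistab import reliability


def anova_mean_squares(X):
    """Independent oracle: two-way ANOVA mean squares via statsmodels OLS."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n, k = X.shape
    df = pd.DataFrame({
        "y": X.ravel(),
        "subject": np.repeat(np.arange(n), k).astype(str),
        "session": np.tile(np.arange(k), n).astype(str),
    })
    tab = sm.stats.anova_lm(ols("y ~ C(subject) + C(session)", df).fit(), typ=2)
    msr = tab.loc["C(subject)", "sum_sq"] / tab.loc["C(subject)", "df"]
    msc = tab.loc["C(session)", "sum_sq"] / tab.loc["C(session)", "df"]
    mse = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
    return msr, msc, mse


class TestVarianceComponents:
    def test_toy_table_matches_anova_oracle(self):
        X = np.array([[1.0, 2.0], [3.0, 5.0], [2.0, 2.5], [6.0, 4.0]])
        vc = reliability.variance_components(X)
        msr, msc, mse = anova_mean_squares(X)
        assert vc.between == pytest.approx(msr, rel=1e-10)
        assert vc.within == pytest.approx(msc, rel=1e-10)
        assert vc.error == pytest.approx(mse, rel=1e-10)

    def test_random_tables_match_anova_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(3, 12)
            X = rng.normal(size=(n, 2))
            vc = reliability.variance_components(X)
            msr, msc, mse = anova_mean_squares(X)
            np.testing.assert_allclose(
                [vc.between, vc.within, vc.error], [msr, msc, mse],
                rtol=1e-10, atol=1e-12)

    def test_duplicate_sessions_give_pure_between(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        vc = reliability.variance_components(np.column_stack([x, x]))
        assert vc.within == pytest.approx(0.0, abs=1e-12)
        assert vc.error == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(vc.proportions, (1.0, 0.0, 0.0), atol=1e-12)

    def test_identical_subjects_with_session_shift_give_zero_between(self):
        X = np.column_stack([np.full(5, 2.0), np.full(5, 3.0)])
        vc = reliability.variance_components(X)
        assert vc.between == pytest.approx(0.0, abs=1e-12)
        assert vc.within > 0

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            reliability.variance_components(np.ones((4, 2)))

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=30)
    def test_proportions_always_sum_to_one(self, seed):
        X = np.random.default_rng(seed).normal(size=(6, 2))
        vc = reliability.variance_components(X)
        assert sum(vc.proportions) == pytest.approx(1.0, abs=1e-9)
        assert all(p >= 0 for p in vc.proportions)


class TestICC:
    def test_duplicate_sessions_icc_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        res = reliability.icc_a1(np.column_stack([x, x]))
        assert res.icc_a1 == pytest.approx(1.0)
        assert res.label == "excellent"

    def test_session_shift_penalised_by_absolute_agreement(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        base = np.column_stack([x, x + rng.normal(0, 0.2, 30)])
        shifted = base.copy()
        shifted[:, 1] += 1.0
        assert (reliability.icc_a1(shifted).icc_a1
                < reliability.icc_a1(base).icc_a1)

    def test_toy_table_matches_formula_from_anova_oracle(self):
        X = np.array([[1.0, 2.0], [3.0, 5.0], [2.0, 2.5], [6.0, 4.0]])
        msr, msc, mse = anova_mean_squares(X)
        n, k = X.shape
        expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert reliability.icc_a1(X).icc_a1 == pytest.approx(expected, rel=1e-10)

    def test_matches_pingouin_icc2_with_ci(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        subj = rng.normal(size=25)
        X = np.column_stack([subj + rng.normal(0, 0.5, 25),
                             subj + 0.3 + rng.normal(0, 0.5, 25)])
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(25), 2),
            "session": np.tile([1, 2], 25),
            "y": X.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="session",
                                       ratings="y").set_index("Type")
        ours = reliability.icc_a1(X)
        assert ours.icc_a1 == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-6)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]  # pingouin rounds to 2 dp
        assert ours.ci_low == pytest.approx(lo, abs=0.011)
        assert ours.ci_high == pytest.approx(hi, abs=0.011)

    def test_monotone_in_between_subject_spread(self):
        # scaling subject effects up never decreases ICC(A,1)
        rng = np.random.default_rng(3)
        subj = rng.normal(size=40)
        noise = rng.normal(0, 1.0, size=(40, 2))
        iccs = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            X = scale * subj[:, None] + noise
            iccs.append(reliability.icc_a1(X).icc_a1)
        assert all(b >= a for a, b in zip(iccs, iccs[1:]))

    @pytest.mark.parametrize("icc,label", [
        (0.1, "poor"), (0.45, "fair"), (0.7, "good"), (0.8, "excellent"),
        (0.4, "fair"), (0.6, "good"), (0.75, "excellent")])
    def test_interpretation_thresholds(self, icc, label):
        assert reliability.icc_label(icc) == label


def _mean_y(df):
    return float(df["y"].mean())


class TestSplitHalf:
    def _trials(self, values_by_subject):
        rows = []
        for sid, vals in values_by_subject.items():
            for v in vals:
                rows.append({"subject_id": sid, "y": v})
        return pd.DataFrame(rows)

    def test_identical_halves_give_unity(self):
        trials = self._trials({f"s{i}": [float(i)] * 20 for i in range(8)})
        est = reliability.split_half(trials, _mean_y, n_splits=10, rng=0)
        assert est == pytest.approx(1.0)

    def test_pure_noise_measure_near_zero(self):
        rng = np.random.default_rng(0)
        trials = self._trials({f"s{i}": list(rng.normal(0, 1, 60))
                               for i in range(40)})
        est = reliability.split_half(trials, _mean_y, n_splits=200, rng=1)
        assert abs(est) < 0.15

    def test_known_variance_ratio_recovered(self):
        # subject means vary with var_b; per-trial noise var_e. A half of
        # m trials has reliability var_b / (var_b + var_e/m); after
        # Spearman-Brown the expected estimate doubles the test length.
        rng = np.random.default_rng(7)
        var_b, var_e, m = 1.0, 4.0, 30
        trials = self._trials({
            f"s{i}": list(rng.normal(rng.normal(0, np.sqrt(var_b)),
                                     np.sqrt(var_e), 2 * m))
            for i in range(150)})
        est = reliability.split_half(trials, _mean_y, n_splits=50, rng=2)
        r_half = var_b / (var_b + var_e / m)
        expected = 2 * r_half / (1 + r_half)
        assert est == pytest.approx(expected, abs=0.08)

    def test_too_few_trials_rejected(self):
        trials = self._trials({"s1": [1.0]})
        with pytest.raises(ValueError, match="at least 2"):
            reliability.split_half(trials, _mean_y, n_splits=5, rng=0)


class TestBetweenSessionCorrelations:
    def test_duplicate_sessions_r_one(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 9.0])
        out = reliability.between_session_correlations(np.column_stack([x, x]))
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_independent_sessions_near_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(500, 2))
        out = reliability.between_session_correlations(X)
        assert abs(out["pearson_r"]) < 0.1

    def test_toy_table_matches_hand_rank_correlation(self):
        # ranks of session 2 against session 1: d = (0, 1, -1, 0, 0)
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 12/120 = 0.9
        X = np.array([[1.0, 10.0], [2.0, 30.0], [3.0, 20.0],
                      [4.0, 40.0], [5.0, 50.0]])
        out = reliability.between_session_correlations(X)
        assert out["spearman_rho"] == pytest.approx(0.9)

    def test_constant_column_flagged(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        out = reliability.between_session_correlations(X)
        assert out["degenerate"] is True
        assert np.isnan(out["pearson_r"])

    def test_long_format_input(self):
        df = pd.DataFrame({
            "subject_id": ["a", "a", "b", "b", "c", "c"],
            "session": [1, 2, 1, 2, 1, 2],
            "value": [1.0, 1.1, 2.0, 2.2, 3.0, 3.1],
        })
        out = reliability.between_session_correlations(df)
        assert out["pearson_r"] > 0.99
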