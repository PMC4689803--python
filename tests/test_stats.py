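"""Cohort statistics: reliability, dependent correlations, regression,
resampling, and subset curves."""

import math

import numpy as np
import pandas as pd
import pytest

from ansddm.chi2fit import FitConfig
from ansddm.stats import (
    half_cohort_resampling,
    inverse_efficiency,
    pearson,
    regression_math,
    split_half_reliability,
    steiger_test,
    subset_reliability_curve,
)


class TestPearson:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, _ = pearson(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        oracle = float(np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2)))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_p_value_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            _, p = pearson(rng.normal(size=12), rng.normal(size=12))
            assert 0 <= p <= 1


class TestSplitHalf:
    def test_identical_halves(self):
        assert split_half_reliability([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_spearman_brown_closed_form(self):
        # construct halves with r exactly 0.5
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])
        z = (x + math.sqrt(3) * y) / 2  # corr(x, z) = 0.5
        r = np.corrcoef(x, z)[0, 1]
        assert r == pytest.approx(0.5, abs=1e-12)
        assert split_half_reliability(x, z) == pytest.approx(2 / 3, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            split_half_reliability([1, 1, 1], [1, 2, 3])


class TestSteiger:
    def test_equal_correlations_give_zero(self):
        z, p = steiger_test(0.4, 0.4, 0.2, 50)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_statistic_grows_with_n(self):
        zs = [abs(steiger_test(0.5, 0.2, 0.3, n)[0]) for n in (20, 80, 320)]
        assert zs[0] < zs[1] < zs[2]

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            steiger_test(0.9, -0.9, 0.9, 50)

    def test_null_calibration(self):
        """Type-I error near nominal 5% for trivariate Gaussians with equal
        dependent correlations (Monte-Carlo oracle)."""
        rng = np.random.default_rng(11)
        cov = np.array([[1, 0.4, 0.4], [0.4, 1, 0.3], [0.4, 0.3, 1]])
        L = np.linalg.cholesky(cov)
        n, reps, rejections = 60, 2000, 0
        for _ in range(reps):
            xyz = rng.standard_normal((n, 3)) @ L.T
            c = np.corrcoef(xyz, rowvar=False)
            _, p = steiger_test(c[0, 1], c[0, 2], c[1, 2], n)
            rejections += p < 0.05
        assert 0.025 < rejections / reps < 0.08


class TestRegression:
    @staticmethod
    def _cohort(rng, n=80, rho=0.0):
        v = rng.normal(1.2, 0.47, n)
        logw = -0.8 * v + rng.normal(0, 0.3, n)
        noise = rng.standard_normal(n)
        math_score = 40 + 10 * (rho * (v - v.mean()) / v.std()
                                + math.sqrt(1 - rho**2) * noise)
        return pd.DataFrame({"v_S": v, "log_w": logw, "math": math_score})

    def test_type_one_error_controlled(self):
        rng = np.random.default_rng(21)
        rejections = 0
        for _ in range(200):
            reg = regression_math(self._cohort(rng), ["v_S", "log_w"])
            rejections += float(reg[reg.term == "v_S"].p.iloc[0]) < 0.05
        assert 0.01 <= rejections / 200 <= 0.12

    def test_power_with_true_association(self):
        rng = np.random.default_rng(22)
        hits = 0
        for _ in range(50):
            reg = regression_math(self._cohort(rng, rho=0.4), ["v_S", "log_w"])
            hits += float(reg[reg.term == "v_S"].p.iloc[0]) < 0.05
        assert hits / 50 > 0.5

    def test_collinear_predictors_rejected(self):
        tab = self._cohort(np.random.default_rng(23))
        tab["v_S_copy"] = tab["v_S"]
        with pytest.raises(ValueError, match="rank-deficient"):
            regression_math(tab, ["v_S", "v_S_copy"])

    def test_r_squared_reported(self):
        reg = regression_math(self._cohort(np.random.default_rng(24), rho=0.5), ["v_S"])
        assert 0 <= reg.attrs["r_squared"] <= 1


class TestInverseEfficiency:
    def test_closed_forms(self):
        assert inverse_efficiency(0.5, 1.0) == 0.5
        assert inverse_efficiency(0.5, 0.5) == 1.0

    def test_monotone_in_accuracy(self):
        assert inverse_efficiency(0.5, 0.7) > inverse_efficiency(0.5, 0.9)

    def test_zero_accuracy_undefined(self):
        with pytest.raises(ValueError):
            inverse_efficiency(0.5, 0.0)


def _resampling_table(n=40, seed=0, deterministic=False):
    rng = np.random.default_rng(seed)
    v = rng.normal(1.2, 0.47, n)
    log_w = -0.8 * v + rng.normal(0, 0.4, n)
    tab = pd.DataFrame({
        "participant_id": [f"P{i:03d}" for i in range(n)],
        "accuracy": rng.uniform(0.65, 0.95, n),
        "mean_rt": rng.uniform(0.4, 0.9, n),
        "v_S": v,
        "w": np.exp(log_w),
        "math": 3 * v if deterministic else 3 * v + rng.normal(0, 2, n),
    })
    return tab


class TestResampling:
    def test_deterministic_math_always_won_by_drift_scale(self):
        res = half_cohort_resampling(_resampling_table(deterministic=True),
                                     reps=300, subset_n=20, seed=1)
        assert res.n_nonsignificant > 0
        assert res.fraction_vs_wins == 1.0

    def test_zero_reps_is_empty(self):
        res = half_cohort_resampling(_resampling_table(), reps=0, subset_n=20)
        assert res.n_nonsignificant == 0
        assert math.isnan(res.fraction_vs_wins)

    def test_row_order_invariance(self):
        tab = _resampling_table()
        shuffled = tab.sample(frac=1.0, random_state=99)
        a = half_cohort_resampling(tab, reps=200, subset_n=20, seed=3)
        b = half_cohort_resampling(shuffled, reps=200, subset_n=20, seed=3)
        assert (a.n_nonsignificant, a.n_vs_wins) == (b.n_nonsignificant, b.n_vs_wins)

    def test_oversized_subset_rejected(self):
        with pytest.raises(ValueError, match="subset_n"):
            half_cohort_resampling(_resampling_table(n=10), reps=10, subset_n=11)


class TestSubsetCurve:
    def test_full_size_matches_direct_estimates(self, cohort20_groups, cohort20):
        _, truth = cohort20
        math_scores = dict(zip(truth.participant_id, truth.math))
        curve = subset_reliability_curve(
            cohort20_groups, math_scores, sizes=(128, 768), estimators=("weber",),
        )
        assert set(curve["size"]) == {128, 768}
        full = curve[curve["size"] == 768].iloc[0]
        # identity subset: reliability equals the all-trials even/odd split
        direct = subset_reliability_curve(cohort20_groups, None, sizes=(768,),
                                          estimators=("weber",)).iloc[0]
        assert full.reliability == pytest.approx(direct.reliability, abs=1e-12)
        assert -1 <= full.reliability <= 1
        assert "r_math" in curve.columns

    def test_reliability_improves_with_more_trials(self, cohort20_groups):
        curve = subset_reliability_curve(cohort20_groups, None, sizes=(128, 768),
                                         estimators=("weber",))
        r128 = curve[curve["size"] == 128].reliability.iloc[0]
        r768 = curve[curve["size"] == 768].reliability.iloc[0]
        assert r768 > r128

    def test_tiny_subset_skipped_with_warning(self, cohort20_groups):
        one = {"P001": cohort20_groups["P001"]}
        with pytest.warns(UserWarning, match="skipped"):
            curve = subset_reliability_curve(one, None, sizes=(1,), estimators=("weber",))
        assert curve.empty
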