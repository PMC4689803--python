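"""First-passage machinery and across-trial mixture predictions."""

import math

import numpy as np
import pytest

from ansddm.ddm import (
    DiffusionParams,
    _cdf_lower_large,
    _cdf_lower_small,
    absorption_prob,
    drift_rate,
    fpt_cdf,
    predict_condition,
)
from ansddm.simulate import simulate_batch, simulate_condition


class TestDriftRate:
    @pytest.mark.parametrize("ratio,expected", [
        ((4, 3), 0.33), ((7, 6), 0.18), ((9, 8), 0.14), ((10, 9), 0.12),
    ])
    def test_published_worked_example(self, ratio, expected):
        """A drift scale of 1.16 maps onto the four published drift rates."""
        assert round(drift_rate(1.16, *ratio), 2) == expected

    def test_zero_scale(self):
        assert drift_rate(0.0, 4, 3) == 0.0

    def test_domain(self):
        with pytest.raises(ValueError):
            drift_rate(1.0, 3, 4)


class TestAbsorption:
    def test_symmetric_start_no_drift(self):
        assert absorption_prob(0.0, 0.093, 0.0465) == pytest.approx(0.5)

    def test_continuity_at_zero_drift(self):
        assert absorption_prob(1e-12, 0.093, 0.03) == pytest.approx(0.03 / 0.093, rel=1e-6)

    def test_strong_drift_limits(self):
        assert absorption_prob(5.0, 0.093, 0.0465) == pytest.approx(1.0, abs=1e-12)
        assert absorption_prob(-5.0, 0.093, 0.0465) == pytest.approx(0.0, abs=1e-12)

    def test_against_path_simulation(self):
        """Closed form matches bridge-corrected path simulation within 3 SE."""
        v, a, z = 0.33, 0.093, 0.0465
        p = DiffusionParams(a=a, s_Z=0.0, v_S=0.0, eta=0.0, T_ER=0.3, s_T=0.0, p_O=0.0)
        out = simulate_batch(p, v, 100_000, seed=123)
        pred = absorption_prob(v, a, z)
        se = math.sqrt(pred * (1 - pred) / out.correct.size)
        assert abs(out.accuracy - pred) < 3 * se

    def test_domain(self):
        with pytest.raises(ValueError):
            absorption_prob(0.1, 0.09, 0.09)


class TestFptCdf:
    def test_zero_at_origin(self):
        assert fpt_cdf(0.0, "correct", 0.3, 0.093, 0.0465) == 0.0
        assert fpt_cdf(0.0, "error", 0.3, 0.093, 0.0465) == 0.0

    def test_conservation_at_infinity(self):
        v, a, z = 0.2, 0.093, 0.0465
        total = fpt_cdf(50.0, "correct", v, a, z) + fpt_cdf(50.0, "error", v, a, z)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert fpt_cdf(50.0, "correct", v, a, z) == pytest.approx(
            absorption_prob(v, a, z), abs=1e-9)

    @pytest.mark.parametrize("v", [-0.6, 0.0, 0.12, 0.33])
    @pytest.mark.parametrize("t", [1e-3, 0.02, 0.1, 0.4, 2.0])
    def test_series_branches_agree(self, v, t):
        """Image-sum and eigenfunction series give the same CDF."""
        a, s = 0.093, 0.1
        for z in (0.25 * a, 0.5 * a, 0.8 * a):
            small = _cdf_lower_small(t, v, a, z, s, 1e-9, 100_000)
            large = _cdf_lower_large(t, v, a, z, s, 1e-9, 100_000)
            assert small == pytest.approx(large, abs=1e-6)

    def test_against_empirical_cdf(self):
        """Analytic defective CDF within the DKW 99% band of 3e5 simulated passages."""
        v, a, z = 0.18, 0.093, 0.0465
        n = 300_000
        p = DiffusionParams(a=a, s_Z=0.0, v_S=0.0, eta=0.0, T_ER=0.3, s_T=0.0, p_O=0.0)
        out = simulate_batch(p, v, n, seed=7, rt_cap=11.0)
        dec = out.rt - 0.3  # constant non-decision time
        eps = math.sqrt(math.log(2 / 0.01) / (2 * n))
        grid = np.linspace(0.01, 2.0, 60)
        for resp, sel in (("correct", out.correct), ("error", ~out.correct)):
            emp = np.array([(sel & (dec <= t)).mean() for t in grid])
            ana = fpt_cdf(grid, resp, v, a, z)
            assert np.max(np.abs(emp - ana)) < eps


@pytest.fixture(scope="module")
def table_pred(table_params):
    return {r: predict_condition(table_params, r) for r in ((4, 3), (10, 9))}


class TestPredictCondition:
    def test_degenerate_mixture_reduces_to_pure_process(self):
        p = DiffusionParams(a=0.093, s_Z=0.0, v_S=1.163, eta=0.0,
                            T_ER=0.4, s_T=0.0, p_O=0.0)
        pred = predict_condition(p, (4, 3))
        v = drift_rate(1.163, 4, 3)
        assert pred.p_correct == pytest.approx(absorption_prob(v, p.a, p.z), abs=1e-12)
        for t in (0.45, 0.55, 0.8):
            assert pred.cdf(t, "correct") == pytest.approx(
                fpt_cdf(t - 0.4, "correct", v, p.a, p.z), abs=1e-9)

    def test_accuracy_monotone_in_ratio(self, table_pred):
        assert table_pred[(4, 3)].p_correct > table_pred[(10, 9)].p_correct

    def test_conservation_with_contaminant(self, table_pred):
        cuts = np.array([0.4, 0.5, 0.6, 0.8, 1.2])
        pc, pe = table_pred[(4, 3)].bin_probabilities(cuts, cuts)
        assert np.all(pc >= 0) and np.all(pe >= 0)
        assert pc.sum() + pe.sum() == pytest.approx(1.0, abs=1e-6)

    def test_cdf_nondecreasing_to_response_probability(self, table_pred):
        pred = table_pred[(10, 9)]
        ts = np.linspace(0.05, 6.0, 80)
        for resp, pr in (("correct", pred.p_correct), ("error", 1 - pred.p_correct)):
            c = pred.cdf(ts, resp)
            assert np.all(np.diff(c) >= -1e-12)
            assert c[-1] == pytest.approx(pr, abs=1e-6)

    def test_monotone_in_caution_and_scale(self, table_params):
        base = predict_condition(table_params, (7, 6)).p_correct
        import dataclasses

        wider = dataclasses.replace(table_params, a=table_params.a * 1.5)
        assert predict_condition(wider, (7, 6)).p_correct > base
        keener = dataclasses.replace(table_params, v_S=table_params.v_S * 1.5)
        assert predict_condition(keener, (7, 6)).p_correct > base

    def test_gauge_invariance(self, table_params):
        """Scaling a, s_Z, v_S, eta and s together leaves predictions unchanged."""
        import dataclasses

        c = 3.7
        scaled = dataclasses.replace(
            table_params, a=table_params.a * c, s_Z=table_params.s_Z * c,
            v_S=table_params.v_S * c, eta=table_params.eta * c, s=table_params.s * c,
        )
        p1 = predict_condition(table_params, (4, 3))
        p2 = predict_condition(scaled, (4, 3))
        assert p2.p_correct == pytest.approx(p1.p_correct, abs=1e-10)
        ts = np.array([0.4, 0.5, 0.7, 1.0])
        assert p2.cdf(ts, "correct") == pytest.approx(p1.cdf(ts, "correct"), abs=1e-8)

    def test_quadrature_refinement(self, table_params):
        """Doubling the node count moves bin probabilities by < 1e-5."""
        cuts = np.array([0.42, 0.48, 0.53, 0.6, 0.75])
        for ratio in ((4, 3), (10, 9)):
            a = predict_condition(table_params, ratio, n_nodes=11)
            b = predict_condition(table_params, ratio, n_nodes=22)
            pa = np.concatenate(a.bin_probabilities(cuts, cuts))
            pb = np.concatenate(b.bin_probabilities(cuts, cuts))
            assert np.max(np.abs(pa - pb)) < 1e-5

    def test_caution_slows_mean_rt(self, table_params):
        """Wider boundaries produce slower correct responses."""
        import dataclasses

        wide = dataclasses.replace(table_params, a=table_params.a * 1.5)
        narrow = simulate_condition(table_params, 7, 6, 30_000, 5)
        cautious = simulate_condition(wide, 7, 6, 30_000, 6)
        assert cautious.rt[cautious.correct].mean() > narrow.rt[narrow.correct].mean()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            predict_condition(DiffusionParams(0.093, 0.1, 1.0, 0.1, 0.4, 0.2, 0.0), (4, 3))
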