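"""Behavioral metrics against brute-force oracles and analytic cases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from timingcircuit.metrics import (asynchrony_and_phase, rmse, bias_var,
                                   bias_by_index, pythagorean_error,
                                   rayleigh_test, linear_fit_r2,
                                   wrap_phase_deg, circular_mean_deg)


class TestAsynchronyAndPhase:
    def test_exact_coincidence(self):
        m = asynchrony_and_phase([1000.0, 1500.0], [1000.0, 1500.0, 2000.0])
        np.testing.assert_allclose(m.asynchronies, [0.0, 0.0])
        np.testing.assert_allclose(m.phases, [0.0, 0.0])

    def test_direct_phase_evaluation(self):
        # a = 10 ms at ISI 500 -> 7.2 degrees
        m = asynchrony_and_phase([1010.0], [1000.0, 1500.0])
        assert m.asynchronies[0] == 10.0
        assert m.phases[0] == pytest.approx(7.2)

    def test_half_period_wraps_to_minus_180(self):
        m = asynchrony_and_phase([750.0], [1000.0, 1500.0])
        assert m.asynchronies[0] == -250.0
        assert m.phases[0] == -180.0

    def test_wrapping_rule_exhaustive(self):
        # oracle: smallest congruent angle in [-180, 180)
        for phi in np.arange(-720.0, 720.0, 7.3):
            w = wrap_phase_deg(phi)
            assert -180.0 <= w < 180.0
            assert (w - phi) % 360.0 == pytest.approx(0.0, abs=1e-9) or \
                   (w - phi) % 360.0 == pytest.approx(360.0, abs=1e-9)

    def test_nearest_matching_brute_force(self):
        rng = np.random.default_rng(0)
        prods = np.sort(rng.uniform(0, 10_000, 20))
        stims = np.sort(rng.uniform(0, 10_000, 8))
        stims += np.arange(8) * 1e-3  # ensure strictly increasing
        m = asynchrony_and_phase(prods, stims)
        for i, s in enumerate(stims[:-1]):
            d = np.abs(prods - s)
            j = np.nonzero(d == d.min())[0][0]  # tie -> earlier production
            assert m.matched_production[i] == j

    def test_skipped_beats_counted(self):
        m = asynchrony_and_phase([1000.0], [990.0, 1490.0, 1990.0])
        assert m.n_shared_matches == 1

    def test_translation_invariance(self):
        prods = np.array([900.0, 1700.0, 2500.0])
        stims = np.array([1000.0, 1800.0, 2600.0])
        a = asynchrony_and_phase(prods, stims)
        b = asynchrony_and_phase(prods + 12_345.0, stims + 12_345.0)
        np.testing.assert_allclose(a.asynchronies, b.asynchronies)
        np.testing.assert_allclose(a.phases, b.phases)

    def test_phase_asynchrony_consistency(self):
        rng = np.random.default_rng(4)
        prods = np.sort(rng.uniform(0, 20_000, 25))
        stims = np.arange(500.0, 19_000.0, 800.0)
        m = asynchrony_and_phase(prods, stims)
        isis = np.diff(stims)
        raw = 360.0 * m.asynchronies / isis
        np.testing.assert_allclose(wrap_phase_deg(raw), m.phases)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            asynchrony_and_phase([], [100.0, 200.0])


class TestRmse:
    def test_cases_and_brute_force(self):
        assert rmse([800.0, 900.0], [800.0, 900.0]) == 0.0
        assert rmse([900.0], [800.0]) == 100.0
        rng = np.random.default_rng(1)
        a, b = rng.normal(800, 50, 40), rng.normal(800, 50, 40)
        direct = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 40)
        assert rmse(a, b) == pytest.approx(direct)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestBiasVar:
    def test_unbiased_noiseless(self):
        b2, v = bias_var({600.0: np.full(5, 600.0), 800.0: np.full(5, 800.0)})
        assert b2 == 0.0 and v == 0.0

    def test_constant_offset(self):
        table = {ts: np.full(4, ts + 50.0) for ts in (600.0, 800.0, 1000.0)}
        b2, v = bias_var(table)
        assert b2 == pytest.approx(2500.0)
        assert v == pytest.approx(0.0)

    def test_brute_force_general_table(self):
        rng = np.random.default_rng(2)
        table = {ts: rng.normal(ts, 30, 50) for ts in (600.0, 800.0, 1000.0)}
        b2, v = bias_var(table)
        b2_ref = np.mean([(x.mean() - ts) ** 2 for ts, x in table.items()])
        v_ref = np.mean([x.var(ddof=1) for x in table.values()])
        assert b2 == pytest.approx(b2_ref)
        assert v == pytest.approx(v_ref)

    def test_decomposition_identity(self):
        # BIAS^2 + VAR equals the MSE of t_p about t_s with matched
        # conventions (conditional means, ddof-1 variances)
        rng = np.random.default_rng(3)
        table = {ts: rng.normal(ts - 40, 25, 200) for ts in
                 (600.0, 700.0, 800.0)}
        b2, v = bias_var(table)
        mse = np.mean([
            ((x - x.mean()) ** 2).sum() / (len(x) - 1) + (x.mean() - ts) ** 2
            for ts, x in table.items()])
        assert b2 + v == pytest.approx(mse)


class TestBiasByIndex:
    def test_perfect_tracking_zero(self):
        table = {isi: np.tile(isi, (10, 6)) for isi in (600.0, 800.0)}
        for k in range(6):
            assert bias_by_index(table, k) == 0.0

    def test_single_trial_degenerate(self):
        table = {700.0: np.array([[750.0, 720.0]])}
        assert bias_by_index(table, 0) == pytest.approx(2500.0)

    def test_brute_force_random_table(self):
        rng = np.random.default_rng(5)
        table = {isi: rng.normal(isi, 40, (21, 8))
                 for isi in (550.0, 683.0, 817.0)}
        for k in (0, 3, 7):
            ref = np.mean([(t[:, k].mean() - isi) ** 2
                           for isi, t in table.items()])
            assert bias_by_index(table, k) == pytest.approx(ref)


class TestPythagoreanError:
    def test_cases(self):
        assert pythagorean_error(0.0, 0.0) == 0.0
        assert pythagorean_error(30.0, 40.0) == 50.0
        assert pythagorean_error(40.0, 30.0) == pythagorean_error(30.0, 40.0)


class TestRayleigh:
    def test_concentrated_rejects(self):
        R, p, mu, sd = rayleigh_test(np.full(50, -27.0))
        assert R == pytest.approx(1.0)
        assert p < 1e-6
        assert mu == pytest.approx(-27.0)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_uniform_grid_resultant_vanishes(self):
        phases = np.linspace(-180.0, 180.0, 360, endpoint=False)
        R, p, _, _ = rayleigh_test(phases)
        assert R == pytest.approx(0.0, abs=1e-10)
        assert p > 0.9

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            _, p, _, _ = rayleigh_test(rng.uniform(-180, 180, 50))
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.03 < rate < 0.07  # ~3 SE band around 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test([0.0, 10.0, 20.0])

    def test_circular_mean_wraps(self):
        assert circular_mean_deg([170.0, -170.0]) == pytest.approx(-180.0)


class TestLinearFit:
    def test_perfect_line(self):
        x = np.arange(10.0)
        slope, intercept, r2, F, p = linear_fit_r2(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_response(self):
        _, _, r2, F, _ = linear_fit_r2(np.arange(10.0), np.full(10, 3.0))
        assert r2 == 0.0

    def test_agrees_with_normal_equations(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 80)
        y = 3 * x + rng.normal(0, 0.5, 80)
        slope, intercept, r2, F, p = linear_fit_r2(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        ss_res = resid @ resid
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(beta[1])
        assert intercept == pytest.approx(beta[0])
        assert r2 == pytest.approx(1 - ss_res / ss_tot)
        assert F == pytest.approx((ss_tot - ss_res) / (ss_res / (len(x) - 2)))


@given(shift=st.floats(-1e5, 1e5))
@settings(deadline=None, max_examples=30)
def test_metrics_invariant_to_time_translation(shift):
    prods = np.array([700.0, 1490.0, 2310.0])
    stims = np.array([750.0, 1550.0, 2350.0])
    a = asynchrony_and_phase(prods, stims)
    b = asynchrony_and_phase(prods + shift, stims + shift)
    np.testing.assert_allclose(a.asynchronies, b.asynchronies, atol=1e-6)
    np.testing.assert_allclose(a.phases, b.phases, atol=1e-6)
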