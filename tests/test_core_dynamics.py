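"""Core BCM dynamics: activation, noise, Euler stepping, threshold crossing."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

from timingcircuit.core_dynamics import (CircuitParams, UnitState, SimTrace,
                                         sigmoid, draw_noise, step_bcm,
                                         simulate_bcm)

from conftest import reference_bcm


class TestSigmoid:
    def test_symmetry_and_identity(self):
        assert sigmoid(0.0) == 0.5
        for x in (-7.3, -0.4, 1.9, 42.0):
            assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-12)

    def test_monotone(self):
        x = np.linspace(-10, 10, 201)
        assert np.all(np.diff(sigmoid(x)) > 0)

    def test_against_arbitrary_precision(self):
        # drive of the u unit at u = 0.77 dominance: 6*0.77 - 6*0.2 = 3.42
        x = 3.42
        exact = float(1 / (1 + sympy.exp(-sympy.Rational(342, 100))).evalf(30))
        assert sigmoid(x) == pytest.approx(exact, abs=1e-12)

    def test_saturates_without_overflow(self):
        assert sigmoid(1000.0) == 1.0
        assert sigmoid(-1000.0) == 0.0


class TestDrawNoise:
    def test_zero_sigma_is_zero(self):
        rng = np.random.default_rng(0)
        assert np.all(draw_noise(0.0, 3, rng, 100) == 0.0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            draw_noise(-0.1, 3, np.random.default_rng(0))

    def test_sample_sd_matches(self):
        rng = np.random.default_rng(7)
        x = draw_noise(0.01, 1, rng, 100_000).ravel()
        se = 0.01 / np.sqrt(2 * (len(x) - 1))  # SE of the sample SD
        assert abs(x.std(ddof=1) - 0.01) < 3 * se
        assert abs(x.mean()) < 3 * 0.01 / np.sqrt(len(x))

    def test_same_seed_identical(self):
        a = draw_noise(0.05, 3, np.random.default_rng(11), 50)
        b = draw_noise(0.05, 3, np.random.default_rng(11), 50)
        np.testing.assert_array_equal(a, b)


class TestCircuitParams:
    @pytest.mark.parametrize("kw", [
        {"tau": 0.0}, {"dt": -1.0}, {"dt": 200.0}, {"sigma_n": -0.01},
        {"y0": 0.0}, {"y0": 1.0}, {"pulse_dur": 1.0},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            CircuitParams(**kw)

    def test_noise_discretization_warning(self):
        with pytest.warns(UserWarning, match="per 10 ms step"):
            CircuitParams(dt=5.0, sigma_n=0.01)


class TestStepBcm:
    def test_symmetric_state_stays_symmetric(self, quiet):
        s = UnitState(u=0.4, v=0.4, y=0.1, I=0.75)
        out = step_bcm(s, quiet)
        assert out.u == pytest.approx(out.v, abs=1e-15)

    def test_fixed_point_unchanged(self, quiet):
        # solve the symmetric-weight fixed point by iteration, then verify
        I = 0.75
        u, v = 0.95, 0.25
        for _ in range(2000):
            u_t = float(sigmoid(6 * I - 6 * v))
            v_t = float(sigmoid(6 * I - 6 * u))
            u, v = u + 0.05 * (u_t - u), v + 0.05 * (v_t - v)
        y = u - v
        out = step_bcm(UnitState(u=u, v=v, y=y, I=I), quiet)
        assert out.u == pytest.approx(u, abs=1e-9)
        assert out.v == pytest.approx(v, abs=1e-9)
        assert out.y == pytest.approx(y, abs=1e-9)

    def test_nonfinite_state_raises(self, quiet):
        with pytest.raises(FloatingPointError):
            step_bcm(UnitState(u=np.nan, v=0.2, y=0.5, I=0.75), quiet)

    def test_trajectory_matches_fine_reference(self, quiet):
        state = quiet.initial_state(0.75)
        for _ in range(100):
            state = step_bcm(state, quiet)
        _, u, v, y, _, _ = reference_bcm(0.75, 1000.0)
        assert state.u == pytest.approx(u[-1], abs=1e-2)
        assert state.v == pytest.approx(v[-1], abs=1e-2)
        assert state.y == pytest.approx(y[-1], abs=1e-2)

    @given(u=st.floats(0, 1), v=st.floats(0, 1), I=st.floats(0.5, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_activities_stay_bounded(self, u, v, I):
        # sigmoid drive lies in [0,1], so Euler keeps u, v in [0, 1+dt/tau]
        p = CircuitParams()
        state = UnitState(u=u, v=v, y=0.5, I=I)
        for _ in range(20):
            state = step_bcm(state, p)
            assert -1e-12 <= state.u <= 1 + p.dt / p.tau
            assert -1e-12 <= state.v <= 1 + p.dt / p.tau


class TestSimulateBcm:
    def test_crossing_matches_fine_reference(self, quiet):
        _, cross = simulate_bcm(quiet, 0.75, 3000.0)
        *_, ref_cross = reference_bcm(0.75, 3000.0)
        assert cross is not None
        assert abs(cross - ref_cross) <= quiet.dt

    def test_larger_input_crosses_later(self, quiet):
        _, c_small = simulate_bcm(quiet, 0.75, 5000.0)
        _, c_large = simulate_bcm(quiet, 0.77, 5000.0)
        assert c_small < c_large

    def test_short_duration_no_crossing(self, quiet):
        _, cross = simulate_bcm(quiet, 0.75, 200.0)
        assert cross is None

    def test_zero_noise_bit_reproducible(self, quiet):
        t1, c1 = simulate_bcm(quiet, 0.76, 2000.0)
        t2, c2 = simulate_bcm(quiet, 0.76, 2000.0)
        assert c1 == c2
        np.testing.assert_array_equal(t1.y, t2.y)

    def test_fixed_seed_reproducible(self, params):
        noisy = params.with_(sigma_n=0.01)
        t1, c1 = simulate_bcm(noisy, 0.76, 2000.0, seed=5)
        t2, c2 = simulate_bcm(noisy, 0.76, 2000.0, seed=5)
        assert c1 == c2
        np.testing.assert_array_equal(t1.y, t2.y)

    def test_halving_dt_first_order_convergence(self, quiet):
        _, c10 = simulate_bcm(quiet, 0.75, 3000.0)
        fine = quiet.with_(dt=5.0)
        _, c5 = simulate_bcm(fine, 0.75, 3000.0)
        assert abs(c10 - c5) < 2 * quiet.dt

    def test_y_increases_toward_crossing(self, quiet):
        trace, cross = simulate_bcm(quiet, 0.76, 3000.0)
        k = int(cross / quiet.dt)
        tail = trace.y[20:k]  # after the initial transient
        assert np.all(np.diff(tail) > 0)


class TestSimTrace:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SimTrace(times=np.arange(3.0), u=np.zeros(3), v=np.zeros(3),
                     y=np.zeros(2), I=np.zeros(3), dI=np.zeros(3))

    def test_csv_roundtrip(self, quiet, tmp_path):
        import pandas as pd
        trace, _ = simulate_bcm(quiet, 0.76, 500.0)
        out = tmp_path / "trace.csv"
        trace.write_csv(out, metadata={"I": 0.76, "seed": None})
        frame = pd.read_csv(out)
        assert list(frame.columns) == ["time_ms", "u", "v", "y", "I", "dI",
                                       "event"]
        np.testing.assert_allclose(frame["y"], trace.y)
        assert out.with_suffix(".csv.json").exists()
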