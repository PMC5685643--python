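"""Accumulator mechanics: noiseless determinism, slope adaptation, CV."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rwddm.timer import (
    TimerNotRunningError,
    TimerState,
    crossing_cv,
    first_crossing_times,
    reset,
    simulate_path,
    slope_update,
    start,
    step,
    time_estimate,
)


def _run_noiseless(A, n_steps, dt):
    s = start(TimerState(slope_A=A))
    for _ in range(n_steps):
        s = step(s, dt, 0.0)
    return s


class TestStep:
    def test_noiseless_increment_is_exact(self):
        s = start(TimerState(slope_A=0.0002, noise_m=0.0))
        s = step(s, 10.0, 0.0)
        assert s.psi == pytest.approx(0.002)

    def test_noiseless_crossing_at_theta_over_a(self):
        # A = 1/5000 per ms crosses theta = 1 after exactly 5000 ms
        s = _run_noiseless(1 / 5000, 500, 10.0)
        assert s.psi == pytest.approx(1.0)

    def test_stopped_timer_refuses_to_step(self):
        with pytest.raises(TimerNotRunningError):
            step(TimerState(slope_A=1e-4), 10.0, 0.0)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            step(start(TimerState(slope_A=1e-4)), 0.0, 0.0)

    @given(
        A=st.floats(1e-6, 1e-3),
        k=st.integers(1, 200),
        dt=st.floats(1.0, 50.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_noiseless_psi_linear_in_steps(self, A, k, dt):
        s = start(TimerState(slope_A=A))
        for _ in range(k):
            s = step(s, dt, 0.0)
        assert s.psi == pytest.approx(A * k * dt, rel=1e-9)


class TestReset:
    def test_reset_zeroes_psi_and_keeps_slope(self):
        s = start(TimerState(slope_A=0.0002))
        s = step(s, 10.0, 0.0)
        s = reset(s)
        assert s.psi == 0.0 and not s.running
        assert s.slope_A == 0.0002

    def test_reset_then_restart_reproduces_fresh_trajectory(self):
        a = _run_noiseless(2e-4, 100, 10.0)
        b = start(reset(a))
        for _ in range(100):
            b = step(b, 10.0, 0.0)
        fresh = _run_noiseless(2e-4, 100, 10.0)
        assert b.psi == pytest.approx(fresh.psi)


class TestSlopeUpdate:
    def test_fixed_point_when_psi_equals_theta(self):
        s = TimerState(slope_A=1 / 5000, threshold_theta=1.0)
        assert slope_update(s, 1.0).slope_A == pytest.approx(s.slope_A)

    def test_hand_evaluated_increment(self):
        # alpha_t=0.1, A=1e-6/ms, Psi(t*)=0.005 -> dA = 0.1e-6*0.995/0.005
        s = TimerState(slope_A=1e-6, adapt_rate_alpha_t=0.1)
        out = slope_update(s, 0.005)
        assert out.slope_A - 1e-6 == pytest.approx(1.99e-5, rel=1e-9)

    def test_degenerate_psi_rejected(self):
        s = TimerState(slope_A=1e-6)
        with pytest.raises(ValueError):
            slope_update(s, 0.0)

    def test_noiseless_convergence_matches_closed_form(self):
        # iterating on a constant 5000-ms interval: the recursion is
        # A(n+1) = A + alpha*(theta/t* - A), closed form geometric approach
        alpha, target = 0.1, 1 / 5000
        s = TimerState(slope_A=1e-6, adapt_rate_alpha_t=alpha)
        gaps = []
        for n in range(1, 501):
            s = slope_update(s, s.slope_A * 5000.0)
            expected = target + (1e-6 - target) * (1 - alpha) ** n
            assert s.slope_A == pytest.approx(expected, rel=1e-9)
            gaps.append(abs(s.slope_A - target))
        assert s.slope_A == pytest.approx(target, rel=1e-4)
        assert all(b <= a + 1e-18 for a, b in zip(gaps, gaps[1:]))  # monotone

    def test_slope_encodes_moving_harmonic_average(self):
        # with theta=1, 1/A is the exponential moving harmonic average of
        # the presented intervals; oracle = explicit recursion on rates
        alpha = 0.215
        intervals = [6000.0, 3000.0, 12000.0, 5000.0, 5000.0, 9000.0] * 5
        s = TimerState(slope_A=1e-3, adapt_rate_alpha_t=alpha)
        rate = 1e-3
        for t_k in intervals:
            s = slope_update(s, s.slope_A * t_k)  # noiseless Psi(t*) = A*t*
            rate = rate + alpha * (1.0 / t_k - rate)
            assert 1.0 / s.slope_A == pytest.approx(1.0 / rate, rel=1e-12)


class TestTimeEstimate:
    @pytest.mark.parametrize(
        "psi,A,expected",
        [(1.0, 1 / 5000, 5000.0), (0.0, 1 / 5000, 0.0), (0.5, 1e-4, 5000.0)],
    )
    def test_examples(self, psi, A, expected):
        s = TimerState(slope_A=A, psi=psi)
        assert time_estimate(s) == pytest.approx(expected)


class TestCrossingCV:
    @pytest.mark.parametrize(
        "theta,m,expected", [(1.0, 0.0, 0.0), (1.0, 0.15, 0.15), (4.0, 0.3, 0.15)]
    )
    def test_closed_form(self, theta, m, expected):
        assert crossing_cv(theta, m) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            crossing_cv(0.0, 0.1)

    def test_monte_carlo_cv_matches_closed_form(self):
        # quick sanity at one duration; the three-duration timescale
        # invariance check lives in the acceptance suite
        rng = np.random.default_rng(0)
        t = first_crossing_times(1 / 5000, 1.0, 0.15, 4000, 10.0, rng)
        cv = np.std(t) / np.mean(t)
        assert cv == pytest.approx(0.15, abs=0.01)


class TestSimulatePath:
    def test_matches_explicit_step_loop(self):
        rng1 = np.random.default_rng(42)
        rng2 = np.random.default_rng(42)
        path = simulate_path(2e-4, 50, 10.0, 0.5, rng1)
        s = start(TimerState(slope_A=2e-4, noise_m=0.5))
        for k in range(50):
            s = step(s, 10.0, float(rng2.standard_normal()))
            assert path[k] == pytest.approx(s.psi, rel=1e-12, abs=1e-15)

    def test_reflection_keeps_path_nonnegative(self):
        rng = np.random.default_rng(1)
        path = simulate_path(1e-6, 2000, 10.0, 2.0, rng)
        assert np.all(path >= 0.0)
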