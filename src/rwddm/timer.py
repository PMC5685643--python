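"""Drift-diffusion interval timer (TDDM core).

A stimulus interval is timed by a noisy linear accumulator Psi that starts
at stimulus onset and rises with slope ``A`` until it crosses a fixed
threshold ``theta``.  Intervals are learned not by moving the threshold but
by adapting the slope: after each timed occurrence of the interval the
slope is nudged so that, on average, the crossing happens at the target
time ``t*``.  With threshold 1, ``1/A`` stores an exponential moving
harmonic average of the experienced intervals.

Per accumulation step the increment is

    dPsi = A*dt + m*sqrt(A*dt)*N(0,1)        (diffusion scaling, default)

which gives first-crossing times an inverse-Gaussian distribution with a
coefficient of variation of exactly ``m/sqrt(theta)`` — constant across
timed durations, i.e. timescale invariant.  A literal linear noise term
``m*A*dt*N(0,1)`` is available for sensitivity checks but does not produce
timescale invariance.

Time is measured in milliseconds throughout this module; slopes are per
millisecond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TimerState",
    "step",
    "reset",
    "start",
    "slope_update",
    "time_estimate",
    "crossing_cv",
    "simulate_path",
    "first_crossing_times",
]


@dataclass(frozen=True)
class TimerState:
    """One stimulus's accumulator.

    Parameters
    ----------
    slope_A
        Accumulation rate per millisecond; strictly positive.
    psi
        Current (dimensionless) accumulation.
    threshold_theta
        Crossing level; strictly positive.
    noise_m
        Dimensionless noise factor, >= 0.
    adapt_rate_alpha_t
        Slope adaptation rate, in (0, 1).
    running
        Whether the timer is currently accumulating.
    """

    slope_A: float
    psi: float = 0.0
    threshold_theta: float = 1.0
    noise_m: float = 0.0
    adapt_rate_alpha_t: float = 0.1
    running: bool = False

    def __post_init__(self) -> None:
        if not self.slope_A > 0:
            raise ValueError(f"slope_A must be > 0, got {self.slope_A}")
        if not self.threshold_theta > 0:
            raise ValueError("threshold_theta must be > 0")
        if self.noise_m < 0:
            raise ValueError("noise_m must be >= 0")
        if not 0 < self.adapt_rate_alpha_t < 1:
            raise ValueError("adapt_rate_alpha_t must be in (0, 1)")


class TimerNotRunningError(RuntimeError):
    """Raised when a stopped timer is asked to accumulate."""


def start(state: TimerState) -> TimerState:
    """Begin accumulating (e.g. at stimulus onset)."""
    return replace(state, running=True)


def reset(state: TimerState) -> TimerState:
    """Stop and zero the accumulator; the learned slope persists."""
    return replace(state, psi=0.0, running=False)


def step(
    state: TimerState,
    dt: float,
    noise_draw: float,
    noise_form: str = "diffusion",
) -> TimerState:
    """Advance the accumulator by one time-step of size ``dt`` ms.

    ``noise_draw`` is a standard-normal sample supplied by the caller so
    that all randomness flows from a single seeded generator.  The
    accumulator may rise past the threshold (no ceiling) but is reflected
    at zero, since a pulse count cannot be negative.
    """
    if not state.running:
        raise TimerNotRunningError("step() on a non-running timer")
    if not dt > 0:
        raise ValueError("dt must be > 0")
    drift = state.slope_A * dt
    if noise_form == "diffusion":
        noise = state.noise_m * math.sqrt(drift) * noise_draw
    elif noise_form == "linear":
        noise = state.noise_m * drift * noise_draw
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"unknown noise_form {noise_form!r}")
    return replace(state, psi=max(state.psi + drift + noise, 0.0))


def slope_update(state: TimerState, psi_at_target: float) -> TimerState:
    """Apply the gradient-descent slope correction at the target time.

    dA = alpha_t * A * (theta - Psi(t*)) / Psi(t*)

    Applied once per occurrence of the timed interval (at reinforcement,
    or at stimulus offset when no reinforcer arrives).  In the noiseless
    limit this is an exponential moving average of the target rates
    ``theta/t*``; the fixed point is A = theta/t*.
    """
    if not psi_at_target > 0:
        raise ValueError(
            f"psi_at_target must be > 0 for a slope update, got {psi_at_target}"
        )
    dA = (
        state.adapt_rate_alpha_t
        * state.slope_A
        * (state.threshold_theta - psi_at_target)
        / psi_at_target
    )
    return replace(state, slope_A=state.slope_A + dA)


def time_estimate(state: TimerState) -> float:
    """Current subjective elapsed time, ``Psi / A``, in milliseconds."""
    return state.psi / state.slope_A


def crossing_cv(theta: float, m: float) -> float:
    """Closed-form coefficient of variation of first-crossing times.

    CV = m / sqrt(theta), independent of the timed duration.
    """
    if not theta > 0:
        raise ValueError("theta must be > 0")
    if m < 0:
        raise ValueError("m must be >= 0")
    return m / math.sqrt(theta)


def simulate_path(
    slope_A: float,
    n_steps: int,
    dt: float,
    noise_m: float,
    rng: np.random.Generator,
    noise_form: str = "diffusion",
) -> np.ndarray:
    """Vectorised accumulator trajectory: Psi after steps 1..n_steps.

    Equivalent to ``n_steps`` calls to :func:`step`, including the
    reflection at zero (Skorokhod construction on the cumulative sum).
    """
    drift = slope_A * dt
    if noise_m == 0.0:
        return drift * np.arange(1, n_steps + 1)
    if noise_form == "diffusion":
        scale = noise_m * math.sqrt(drift)
    elif noise_form == "linear":
        scale = noise_m * drift
    else:
        raise ValueError(f"unknown noise_form {noise_form!r}")
    inc = drift + scale * rng.standard_normal(n_steps)
    walk = np.cumsum(inc)
    # reflect at zero: subtract the running minimum where it dips below 0
    floor = np.minimum.accumulate(np.minimum(walk, 0.0))
    return walk - floor


def first_crossing_times(
    slope_A: float,
    theta: float,
    noise_m: float,
    n_runs: int,
    dt: float,
    rng: np.random.Generator,
    max_time_factor: float = 4.0,
) -> np.ndarray:
    """Monte-Carlo first-crossing times (ms) of ``n_runs`` fresh timers.

    Crossing times are linearly interpolated between the bracketing steps
    to reduce discretisation bias.  Runs that never cross within
    ``max_time_factor * theta/A`` are excluded (with drift-dominated
    parameters this is vanishingly rare).
    """
    n_steps = int(max_time_factor * theta / (slope_A * dt))
    drift = slope_A * dt
    scale = noise_m * math.sqrt(drift)
    walks = np.cumsum(
        drift + scale * rng.standard_normal((n_runs, n_steps)), axis=1
    )
    crossed = walks >= theta
    idx = np.argmax(crossed, axis=1)
    ok = crossed[np.arange(n_runs), idx]
    idx = idx[ok]
    after = walks[ok, idx]
    before = np.where(idx > 0, walks[ok, np.maximum(idx - 1, 0)], 0.0)
    frac = (theta - before) / (after - before)
    return (idx + frac) * dt
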