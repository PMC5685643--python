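"""Time-adaptive stimulus representations.

The conditioned stimulus is represented by a single unit whose activation
is a Gaussian radial basis function of the accumulator state, centred on
the timer threshold: activation peaks (at 1) exactly when the accumulator
crosses threshold, i.e. at the remembered interval.  Because the timer
slope adapts, the representation inherits the timer's timescale
invariance.

Two optional variants model early training: a slow narrowing of the
Gaussian width with stimulus exposure, and a leaky-integrator trace that
simply tracks stimulus presence before timing is expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GaussianRepresentation",
    "AdaptiveWidth",
    "LeakyTrace",
    "activation",
    "width_update",
    "leaky_step",
]


@dataclass(frozen=True)
class GaussianRepresentation:
    """Gaussian receptive field over accumulator values."""

    width_sigma: float
    center: float = 1.0  # the owning timer's threshold theta

    def __post_init__(self) -> None:
        if not self.width_sigma > 0:
            raise ValueError("width_sigma must be > 0")


def activation(rep: GaussianRepresentation, psi):
    """exp(-(psi - theta)^2 / (2 sigma^2)); accepts scalars or arrays."""
    d = np.asarray(psi, dtype=float) - rep.center
    out = np.exp(-(d * d) / (2.0 * rep.width_sigma**2))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AdaptiveWidth:
    """Linear-operator narrowing of the Gaussian width with exposure.

    sigma(n+1) = sigma(n) + alpha_sigma * (sigma_target - sigma(n))
    """

    sigma_n: float
    sigma_target: float = 0.35
    rate_alpha_sigma: float = 0.025

    def __post_init__(self) -> None:
        if not self.sigma_n > 0 or not self.sigma_target > 0:
            raise ValueError("widths must be > 0")
        if not 0 < self.rate_alpha_sigma < 1:
            raise ValueError("rate_alpha_sigma must be in (0, 1)")


def width_update(aw: AdaptiveWidth) -> AdaptiveWidth:
    """One per-trial step of the width toward its asymptote."""
    new = aw.sigma_n + aw.rate_alpha_sigma * (aw.sigma_target - aw.sigma_n)
    return replace(aw, sigma_n=new)


@dataclass(frozen=True)
class LeakyTrace:
    """Leaky integrator of stimulus presence: x += (I - x)/tau."""

    x: float = 0.0
    tau: float = 10.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.x < 0:
            raise ValueError("x must be >= 0")


def leaky_step(trace: LeakyTrace, present: float) -> LeakyTrace:
    """Advance the trace one step given the presence indicator (0 or 1)."""
    return replace(trace, x=trace.x + (present - trace.x) / trace.tau)
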