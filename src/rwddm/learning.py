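"""Associative-strength dynamics.

The associative update is the Rescorla-Wagner rule with two changes that
tie it to the timer: the stimulus input is the (time-varying) Gaussian
activation rather than a 0/1 presence code, and the learning asymptote is
set by the remembered time to reinforcement,

    lambda_i = H * A_i / Psi_i(t*)

which spreads the motivational value ``H`` of the reinforcer hyperbolically
over the signalled delay (lambda ~ H / t*).  Slopes enter the asymptote in
s^-1 so that, e.g., H = 5 with a converged 5-second timer gives
lambda = V_inf ~ 1.

An optional Pearce-Hall extension makes the learning rate itself chase the
absolute prediction error, which produces latent inhibition: a preexposed
stimulus arrives at conditioning with its rate decayed toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

__all__ = [
    "AssociativeState",
    "PearceHallState",
    "asymptote",
    "rw_update",
    "response",
    "ph_error",
    "ph_rate_update",
    "steady_state_v",
]


@dataclass(frozen=True)
class AssociativeState:
    """Associative strength for one stimulus representation.

    ``V`` may go negative (conditioned inhibition).  ``H = 0`` encodes US
    absence (extinction).
    """

    V: float = 0.0
    alpha_V: float = 0.1
    H: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_V < 1:
            raise ValueError("alpha_V must be in (0, 1)")
        if self.H < 0:
            raise ValueError("H must be >= 0")


@dataclass(frozen=True)
class PearceHallState:
    """Adaptive learning rate chasing |prediction error|."""

    alpha_V_n: float
    gamma: float = 0.03
    alpha_novel: float = 0.4

    def __post_init__(self) -> None:
        if self.alpha_V_n < 0:
            raise ValueError("alpha_V_n must be >= 0")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must be in (0, 1)")


def asymptote(H: float, A_per_s: float, psi_at_target: float) -> float:
    """Learning asymptote lambda = H * A / Psi(t*), with A in s^-1."""
    if H == 0.0:
        return 0.0
    if not psi_at_target > 0:
        raise ValueError("psi_at_target must be > 0")
    return H * A_per_s / psi_at_target


def rw_update(
    states: Sequence[AssociativeState],
    activations: Sequence[float],
    lambdas: Sequence[float],
) -> list[AssociativeState]:
    """One Rescorla-Wagner step for every representation present.

    dV_i = alpha_V_i * (lambda_i - sum_j V_j x_j) * x_i

    The shared summation term is what lets reinforcement histories compete
    in compounds (blocking, conditioned inhibition).  ``lambdas`` is
    per-stimulus because each timer signals its own remembered delay.
    """
    if not (len(states) == len(activations) == len(lambdas)):
        raise ValueError("states, activations and lambdas must align")
    prediction = sum(s.V * x for s, x in zip(states, activations))
    return [
        replace(s, V=s.V + s.alpha_V * (lam - prediction) * x)
        for s, x, lam in zip(states, activations, lambdas)
    ]


def response(V: float, x: float, floor: bool = True) -> float:
    """Real-time conditioned response, CR = V * x.

    Negative products (inhibition) are floored at 0 when reporting
    behaviour; pass ``floor=False`` for the raw summing-junction value.
    """
    cr = V * x
    return max(cr, 0.0) if floor else cr


def ph_error(
    H: float, A_per_s: float, psi_at_target: float, V: float, x: float
) -> float:
    """Pearce-Hall prediction error delta = lambda - V*x for one stimulus."""
    return asymptote(H, A_per_s, psi_at_target) - V * x


def ph_rate_update(ph: PearceHallState, delta: float) -> PearceHallState:
    """alpha_V(n+1) = alpha_V(n) + gamma * (|delta| - alpha_V(n))."""
    new = ph.alpha_V_n + ph.gamma * (abs(delta) - ph.alpha_V_n)
    return replace(ph, alpha_V_n=new)


def steady_state_v(
    H: float, A_inf_per_s: float, x_at_target: float, psi_at_target: float
) -> float:
    """Asymptotic associative strength V_inf = H * A_inf * x / Psi(t*).

    Expected-value approximation (the accumulation at the target time is a
    random variable; this plugs in typical values).
    """
    if H == 0.0:
        return 0.0
    if not psi_at_target > 0:
        raise ValueError("psi_at_target must be > 0")
    return H * A_inf_per_s * x_at_target / psi_at_target
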