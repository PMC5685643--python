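"""Real-time simulation engine.

Composes the timer, representation and learning modules over a trial
sequence.  Within a trial the accumulators of all present stimuli are
stepped every ``dt`` and the conditioned response is emitted continuously
as V·x(Ψ); at the end of the trial (US delivery, or CS offset on
non-reinforced trials) the per-trial learning rules fire: the
Rescorla-Wagner associative update with the time-set asymptote, and the
timer slope correction.  Peak (probe) trials receive no updates.

Compound handling follows the protocol's policy:

``sum``
    the summing junction — CR is the sum of every present stimulus's
    output (blocking, conditioned inhibition);
``faster_timer``
    responding on simultaneous compounds is guided solely by the stimulus
    whose timer currently has the larger slope (disinhibition of delay,
    compound peak procedure);
``average``
    the compound is processed as a single representation whose rate and
    strength pool half of each component's (temporal averaging); a
    V-weighted pooling variant is available.

A stimulus may own several timer/representation units (mixed FI): at each
instant behaviour is guided by the unit with the highest activation, and
at reinforcement only the maximally active unit is credited.

Accumulator paths are simulated vectorised per trial (mathematically
identical to stepping the public ``timer.step`` rule; the equivalence is
exercised in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import timer as timer_mod
from .learning import rw_update, AssociativeState
from .protocols import ExperimentDesign, GroupDesign, TrialSpec
from .representation import GaussianRepresentation, activation

__all__ = [
    "ModelParams",
    "CSUnit",
    "ModelState",
    "SimulationTrace",
    "ExperimentResult",
    "run_trial",
    "run_group",
    "run_experiment",
    "select_compound_timer",
    "assign_credit_mixed_fi",
    "combine_temporal_average",
    "derive_seed",
]


@dataclass
class ModelParams:
    """Free parameters of the model plus engine switches.

    The six free model parameters are ``m`` (accumulator noise), ``theta``
    (threshold), ``sigma`` (representation width), ``alpha_t`` (timing
    rate), ``alpha_V`` (associative rate) and ``H`` (US motivational
    magnitude).  ``A_init`` is the slope assigned to a novel stimulus, in
    ms^-1 — low enough to overestimate any experimental duration at first.
    ``psi_update_floor`` regularises degenerate early-training trials: the
    accumulation entering the end-of-trial updates is floored at this
    fraction of theta (see docs/methods.md).
    """

    m: float = 0.15
    theta: float = 1.0
    sigma: float = 0.3
    alpha_t: float = 0.1
    alpha_V: float = 0.1
    H: float = 5.0
    dt_ms: float = 10.0
    A_init: float = 1e-6
    noise_form: str = "diffusion"
    compound_policy: str = "sum"
    averaging_weighting: str = "equal"  # "equal" | "v_weighted"
    pearce_hall: bool = False
    ph_alpha_novel: float = 0.4
    ph_gamma: float = 0.03
    adaptive_width: bool = False
    sigma_init: float = 0.6
    sigma_target: float = 0.35
    alpha_sigma: float = 0.025
    psi_update_floor: float = 0.01
    response_floor: bool = True

    def __post_init__(self) -> None:
        if self.noise_form not in ("diffusion", "linear"):
            raise ValueError("noise_form must be 'diffusion' or 'linear'")
        if self.compound_policy not in ("sum", "faster_timer", "average"):
            raise ValueError("bad compound_policy")
        if self.averaging_weighting not in ("equal", "v_weighted"):
            raise ValueError("bad averaging_weighting")
        for name in ("alpha_t", "alpha_V"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not self.dt_ms > 0:
            raise ValueError("dt_ms must be > 0")
        if self.H < 0:
            raise ValueError("H must be >= 0")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "ModelParams":
        return cls(**dict(mapping))


@dataclass
class CSUnit:
    """Mutable per-representation state: one timer + one associative link."""

    label: str
    rep: int
    A: float  # slope, per ms
    V: float = 0.0
    sigma: float = 0.35
    alpha_V: float = 0.1  # adaptive when Pearce-Hall is on


class ModelState:
    """All per-stimulus units plus the parameter set."""

    def __init__(self, params: ModelParams, n_representations: Mapping[str, int] | None = None):
        self.params = params
        self._n_reps = dict(n_representations or {})
        self.units: dict[str, list[CSUnit]] = {}

    def units_for(self, label: str) -> list[CSUnit]:
        """Get (lazily creating) the unit list for a stimulus label."""
        if label not in self.units:
            p = self.params
            n = self._n_reps.get(label, 1)
            sigma0 = p.sigma_init if p.adaptive_width else p.sigma
            alpha0 = p.ph_alpha_novel if p.pearce_hall else p.alpha_V
            self.units[label] = [
                CSUnit(label, r, A=p.A_init, sigma=sigma0, alpha_V=alpha0)
                for r in range(n)
            ]
        return self.units[label]


def select_compound_timer(units: Sequence[CSUnit]) -> CSUnit:
    """The unit guiding responding on a simultaneous compound: largest
    slope; ties broken deterministically by stimulus label order."""
    return min(units, key=lambda u: (-u.A, u.label))


def assign_credit_mixed_fi(
    units: Sequence[CSUnit], activations_at_event: Sequence[float]
) -> int:
    """Index of the representation credited at a reinforcement event: the
    maximally active one (earliest index on ties)."""
    return int(np.argmax(activations_at_event))


def combine_temporal_average(
    a_low: float,
    v_low: float,
    a_high: float,
    v_high: float,
    weighting: str = "equal",
) -> tuple[float, float]:
    """Pool two trained timers into one compound (rate, strength).

    ``equal``: A = A_low/2 + A_high/2 (harmonic averaging of the
    remembered intervals) and V = (V_low + V_high)/2.  ``v_weighted``:
    rates weighted by relative associative strength.
    """
    if weighting == "equal":
        return (a_low + a_high) / 2.0, (v_low + v_high) / 2.0
    if weighting == "v_weighted":
        tot = v_low + v_high
        if tot <= 0:
            raise ValueError("v_weighted pooling needs positive total V")
        a = (v_low / tot) * a_low + (v_high / tot) * a_high
        return a, (v_low + v_high) / 2.0
    raise ValueError(f"unknown weighting {weighting!r}")


@dataclass
class SimulationTrace:
    """Complete record of one group's run."""

    group: str
    seed: int
    dt_ms: float
    params: dict
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)
    units: pd.DataFrame = field(default_factory=pd.DataFrame)
    cr: dict[int, np.ndarray] = field(default_factory=dict)

    def select_trials(
        self,
        trial_type: str | None = None,
        stimuli: Sequence[str] | str | None = None,
        phase: str | None = None,
        recorded_only: bool = False,
    ) -> pd.DataFrame:
        """Filter the per-trial table by type, stimulus set and/or phase."""
        df = self.trials
        if trial_type is not None:
            df = df[df.trial_type == trial_type]
        if stimuli is not None:
            if isinstance(stimuli, str):
                stimuli = (stimuli,)
            key = "+".join(sorted(stimuli))
            df = df[df.stimuli == key]
        if phase is not None:
            df = df[df.phase == phase]
        if recorded_only:
            df = df[df.index.isin(self.cr)]
        return df

    def v_series(self, label: str, rep: int = 0) -> pd.Series:
        """Associative strength of one unit across the trials in which its
        stimulus was present, indexed by trial number."""
        u = self.units
        sel = u[(u.label == label) & (u.rep == rep)]
        return sel.set_index("trial")["V"]


@dataclass
class ExperimentResult:
    design: str
    seed: int
    groups: dict[str, SimulationTrace]

    def __getitem__(self, name: str) -> SimulationTrace:
        return self.groups[name]


def derive_seed(seed: int, index: int) -> int:
    """Deterministic child seed (< 2**31) for group/replication ``index``."""
    return (seed * 1_000_003 + 7_919 * (index + 1)) % (2**31)


def _steps(t_s: float, dt_ms: float) -> int:
    return int(round(t_s * 1000.0 / dt_ms))


@dataclass
class TrialOutcome:
    """Trace segment produced by one trial."""

    cr: np.ndarray | None
    unit_rows: list[dict]
    averaged_unit: tuple[float, float] | None = None  # (A, V) on pooled probes


def run_trial(
    trial: TrialSpec,
    state: ModelState,
    rng: np.random.Generator,
    record: bool = True,
) -> TrialOutcome:
    """Simulate one trial, apply the end-of-trial updates, and return the
    trace segment (per-step CR plus per-unit summary rows)."""
    p = state.params
    dt = p.dt_ms
    n_steps = _steps(trial.trial_duration, dt)
    if n_steps <= 0:
        raise ValueError("trial too short for the configured time-step")

    # --- simulate every present unit's accumulator path -------------------
    paths: dict[tuple[str, int], np.ndarray] = {}
    windows: dict[str, tuple[int, int]] = {}
    for stim in trial.stimuli:
        on = _steps(stim.onset, dt)
        off = min(n_steps, _steps(stim.onset + stim.duration, dt))
        if off <= on:
            raise ValueError(f"stimulus {stim.label} has no active steps")
        windows[stim.label] = (on, off)
        for u in state.units_for(stim.label):
            paths[(u.label, u.rep)] = timer_mod.simulate_path(
                u.A, off - on, dt, p.m, rng, p.noise_form
            )

    def unit_x(u: CSUnit) -> np.ndarray:
        rep = GaussianRepresentation(u.sigma, p.theta)
        return activation(rep, paths[(u.label, u.rep)])

    def cs_output(label: str) -> np.ndarray:
        """Behaviour contribution of one stimulus over its active window:
        V·x of the maximally active representation at each instant."""
        us = state.units_for(label)
        if len(us) == 1:
            return us[0].V * unit_x(us[0])
        xs = np.stack([unit_x(u) for u in us])
        vs = np.array([u.V for u in us])
        sel = np.argmax(xs, axis=0)
        return vs[sel] * xs[sel, np.arange(xs.shape[1])]

    # --- compose the CR time series ---------------------------------------
    labels = [s.label for s in trial.stimuli]
    compound = len(labels) >= 2
    policy = p.compound_policy if compound else "sum"
    cr = np.zeros(n_steps)
    avg_unit: tuple[float, float] | None = None

    if policy == "average":
        ordered = sorted(
            (state.units_for(lb)[0] for lb in labels), key=lambda u: u.A
        )
        low, high = ordered[0], ordered[-1]
        a_c, v_c = combine_temporal_average(
            low.A, low.V, high.A, high.V, p.averaging_weighting
        )
        avg_unit = (a_c, v_c)
        on = min(windows[lb][0] for lb in labels)
        off = max(windows[lb][1] for lb in labels)
        psi_c = timer_mod.simulate_path(a_c, off - on, dt, p.m, rng, p.noise_form)
        rep_c = GaussianRepresentation(p.sigma, p.theta)
        cr[on:off] = v_c * activation(rep_c, psi_c)
    elif policy == "faster_timer":
        chosen = select_compound_timer(
            [state.units_for(lb)[0] for lb in labels]
        )
        on, off = windows[chosen.label]
        cr[on:off] = chosen.V * unit_x(chosen)
    else:
        for lb in labels:
            on, off = windows[lb]
            cr[on:off] += cs_output(lb)

    if p.response_floor:
        cr = np.maximum(cr, 0.0)

    # --- end-of-trial learning updates (never on peak probes) -------------
    unit_rows: list[dict] = []
    if trial.trial_type != "peak":
        H = trial.us_magnitude if trial.us_magnitude is not None else (
            p.H if trial.trial_type == "reinforced" else 0.0
        )
        if trial.trial_type == "extinction":
            H = 0.0
        us_step = (
            _steps(trial.us_time, dt) if trial.trial_type == "reinforced" else None
        )

        # gather the credited unit of every present stimulus
        credited: list[tuple[CSUnit, float, float]] = []  # unit, psi*, x*
        for lb in labels:
            on, off = windows[lb]
            # update marker: US delivery, or this CS's offset in extinction
            t_up = us_step if us_step is not None else off
            idx = min(t_up, off) - on - 1
            if idx < 0:
                continue
            us = state.units_for(lb)
            psis = [paths[(u.label, u.rep)][idx] for u in us]
            xs = [
                activation(GaussianRepresentation(u.sigma, p.theta), ps)
                for u, ps in zip(us, psis)
            ]
            k = assign_credit_mixed_fi(us, xs) if len(us) > 1 else 0
            credited.append((us[k], psis[k], xs[k]))

        # Rescorla-Wagner step with per-stimulus time-set asymptotes
        states = [
            AssociativeState(V=u.V, alpha_V=min(max(u.alpha_V, 1e-12), 1 - 1e-12), H=max(H, 0.0))
            for u, _, _ in credited
        ]
        acts = [x for _, _, x in credited]
        floor = p.psi_update_floor * p.theta
        lambdas = [
            (H * (u.A * 1000.0) / max(psi, floor)) if H > 0 else 0.0
            for u, psi, _ in credited
        ]
        deltas = [lam - u.V * x for lam, (u, _, x) in zip(lambdas, credited)]
        new_states = rw_update(states, acts, lambdas)

        for (u, psi, x), ns, delta in zip(credited, new_states, deltas):
            u.V = ns.V
            # timer slope correction at the trained marker
            psi_eff = max(psi, floor)
            u.A += p.alpha_t * u.A * (p.theta - psi_eff) / psi_eff
            if p.pearce_hall:
                u.alpha_V += p.ph_gamma * (abs(delta) - u.alpha_V)
            if p.adaptive_width:
                u.sigma += p.alpha_sigma * (p.sigma_target - u.sigma)
            unit_rows.append(
                dict(
                    label=u.label,
                    rep=u.rep,
                    A=u.A,
                    V=u.V,
                    psi_t=psi,
                    x_t=x,
                    alpha_V=u.alpha_V,
                    sigma=u.sigma,
                )
            )

    return TrialOutcome(
        cr=cr.astype(np.float32) if record else None,
        unit_rows=unit_rows,
        averaged_unit=avg_unit,
    )


RecordRule = str | Callable[[TrialSpec], bool]


def _should_record(rule: RecordRule, trial: TrialSpec) -> bool:
    if callable(rule):
        return bool(rule(trial))
    if rule == "all":
        return True
    if rule == "none":
        return False
    return trial.trial_type == rule


def run_group(
    group: GroupDesign,
    seed: int,
    overrides: Mapping[str, object] | None = None,
    record: RecordRule = "all",
) -> SimulationTrace:
    """Run all phases of one group, carrying state across phases."""
    params = ModelParams.from_mapping({**group.params, **(overrides or {})})
    rng = np.random.default_rng(seed)
    state = ModelState(params, group.n_representations)

    trial_rows: list[dict] = []
    unit_rows: list[dict] = []
    cr_store: dict[int, np.ndarray] = {}
    i = 0
    for phase in group.phases:
        for trial in phase.realize(rng):
            rec = _should_record(record, trial)
            outcome = run_trial(trial, state, rng, record=rec)
            if rec and outcome.cr is not None:
                cr_store[i] = outcome.cr
            trial_rows.append(
                dict(
                    trial=i,
                    phase=phase.name,
                    trial_type=trial.trial_type,
                    stimuli="+".join(sorted(trial.labels)),
                    duration_s=trial.trial_duration,
                    us_time_s=trial.us_time,
                )
            )
            for row in outcome.unit_rows:
                unit_rows.append({**row, "trial": i, "phase": phase.name})
            i += 1

    return SimulationTrace(
        group=group.name,
        seed=seed,
        dt_ms=params.dt_ms,
        params=asdict(params),
        trials=pd.DataFrame(trial_rows),
        units=pd.DataFrame(unit_rows),
        cr=cr_store,
    )


def run_experiment(
    design: ExperimentDesign,
    seed: int,
    overrides: Mapping[str, object] | None = None,
    record: RecordRule = "all",
    groups: Iterable[str] | None = None,
) -> ExperimentResult:
    """Run every group of a design (each on a derived sub-seed).

    Fully reproducible: the same seed yields bit-identical traces.
    """
    wanted = set(groups) if groups is not None else None
    out: dict[str, SimulationTrace] = {}
    for gi, g in enumerate(design.groups):
        if wanted is not None and g.name not in wanted:
            continue
        out[g.name] = run_group(g, derive_seed(seed, gi), overrides, record)
    if wanted is not None and wanted - set(out):
        raise KeyError(f"unknown groups: {sorted(wanted - set(out))}")
    return ExperimentResult(design.name, seed, out)
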