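"""Experimental designs: trial specifications and the 10 named presets.

Each preset encodes one simulated conditioning experiment — phase
structure, trial counts, stimulus durations, reinforcement times and the
model parameter set used for it.  Trials are declarative; randomness
(trial-order shuffling, variable-interval sampling) is injected at
realization time from the experiment runner's seeded generator.

Conventions: all protocol-level times are in seconds; reinforced trials
end at US delivery (the CS co-terminates with the US unless an onset is
staggered); extinction trials end at CS offset; peak trials are long
non-reinforced probes that receive no learning updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "StimulusSpec",
    "TrialSpec",
    "VITrialTemplate",
    "Phase",
    "GroupDesign",
    "ExperimentDesign",
    "build_design",
    "list_designs",
    "vi_harmonic_mean_reference",
    "PRESET_NAMES",
    "UnknownDesignError",
]


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus presentation within a trial (times in seconds)."""

    label: str
    onset: float
    duration: float
    modality: str = ""

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")


@dataclass(frozen=True)
class TrialSpec:
    """A fully specified trial.

    ``us_magnitude`` of ``None`` means "use the group's H"; extinction and
    peak trials carry no US.
    """

    stimuli: tuple[StimulusSpec, ...]
    trial_type: str  # "reinforced" | "extinction" | "peak"
    trial_duration: float
    us_time: float | None = None
    us_magnitude: float | None = None

    def __post_init__(self) -> None:
        if self.trial_type not in ("reinforced", "extinction", "peak"):
            raise ValueError(f"bad trial_type {self.trial_type!r}")
        if self.trial_type == "reinforced":
            if self.us_time is None:
                raise ValueError("reinforced trial needs us_time")
            if self.us_time > self.trial_duration:
                raise ValueError("us_time must be <= trial_duration")
        elif self.us_time is not None:
            raise ValueError(f"{self.trial_type} trial cannot carry a US")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.stimuli)


@dataclass(frozen=True)
class VITrialTemplate:
    """Reinforced trial whose CS duration is drawn per realization.

    Durations are sampled from the discrete uniform distribution on the
    integers ``lo..hi`` seconds (inclusive).
    """

    label: str
    lo: int
    hi: int

    def realize(self, rng: np.random.Generator) -> TrialSpec:
        d = float(rng.integers(self.lo, self.hi + 1))
        return TrialSpec(
            stimuli=(StimulusSpec(self.label, 0.0, d),),
            trial_type="reinforced",
            trial_duration=d,
            us_time=d,
        )


@dataclass(frozen=True)
class Phase:
    """An ordered (or shuffled) block structure of trials."""

    name: str
    blocks: tuple[tuple[TrialSpec | VITrialTemplate, int], ...]
    shuffle: bool = False

    @property
    def n_trials(self) -> int:
        return sum(count for _, count in self.blocks)

    def realize(self, rng: np.random.Generator) -> list[TrialSpec]:
        """Expand blocks into a concrete trial list for one run."""
        trials: list[TrialSpec] = []
        for template, count in self.blocks:
            for _ in range(count):
                if isinstance(template, VITrialTemplate):
                    trials.append(template.realize(rng))
                else:
                    trials.append(template)
        if self.shuffle:
            perm = rng.permutation(len(trials))
            trials = [trials[i] for i in perm]
        return trials


@dataclass(frozen=True)
class GroupDesign:
    """One group (condition) of an experiment: phases plus parameters."""

    name: str
    phases: tuple[Phase, ...]
    params: Mapping[str, float | str | bool] = field(default_factory=dict)
    n_representations: Mapping[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class ExperimentDesign:
    name: str
    groups: tuple[GroupDesign, ...]
    description: str = ""

    def group(self, name: str) -> GroupDesign:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


class UnknownDesignError(ValueError):
    """Raised for an unrecognized preset name; lists the valid ones."""


def _cs(label: str, dur: float, onset: float = 0.0, modality: str = "") -> StimulusSpec:
    return StimulusSpec(label, onset, dur, modality)


def _fi(label: str, dur: float) -> TrialSpec:
    """Delay-conditioning trial: CS of ``dur`` s co-terminating with the US."""
    return TrialSpec((_cs(label, dur),), "reinforced", dur, us_time=dur)


def _ext(label: str, dur: float) -> TrialSpec:
    return TrialSpec((_cs(label, dur),), "extinction", dur)


def _peak(labels, dur_each: float, trial_dur: float) -> TrialSpec:
    if isinstance(labels, str):
        labels = (labels,)
    stims = tuple(_cs(lb, trial_dur) for lb in labels)
    del dur_each  # probes keep every CS on for the whole trial
    return TrialSpec(stims, "peak", trial_dur)


def vi_harmonic_mean_reference(lo: int = 15, hi: int = 45) -> float:
    """Harmonic mean (s) of the full discrete-uniform interval set.

    The timer's slope stores a *moving* harmonic average of the sampled
    intervals, so this non-moving value is the analytic reference for
    where the variable-interval peak should settle (27.1 s for 15..45 s).
    """
    ks = np.arange(lo, hi + 1, dtype=float)
    return float(len(ks) / np.sum(1.0 / ks))


def _build_acquisition() -> ExperimentDesign:
    # H = 5 makes the steady-state arithmetic V_inf ~ H * A_inf = 1 exact.
    params = dict(m=0.15, theta=1.0, sigma=0.3, alpha_t=0.1, alpha_V=0.1, H=5.0)
    phases = (
        Phase("acquisition", ((_fi("CS", 5.0), 80),)),
        Phase("extinction", ((_ext("CS", 5.0), 100),)),
        Phase("reacquisition", ((_fi("CS", 5.0), 80),)),
    )
    return ExperimentDesign(
        "acquisition_extinction_reacquisition",
        (GroupDesign("FI5", phases, params),),
        "5-s CS: 80 reinforced, 100 extinction, 80 reacquisition trials",
    )


def _build_extinction_duration_change() -> ExperimentDesign:
    params = dict(m=0.25, theta=1.0, sigma=0.35, alpha_t=0.08, alpha_V=0.09, H=30.0)
    groups = []
    for name, ext_dur in (("FI20-40", 40.0), ("FI20-10", 10.0), ("FI20-20", 20.0)):
        groups.append(
            GroupDesign(
                name,
                (
                    Phase("acquisition", ((_fi("CS", 20.0), 150),)),
                    Phase("extinction", ((_ext("CS", ext_dur), 150),)),
                ),
                params,
            )
        )
    return ExperimentDesign(
        "extinction_duration_change",
        tuple(groups),
        "20-s acquisition then extinction at 40, 10 or (control) 20 s",
    )


def _build_isi_effect() -> ExperimentDesign:
    params = dict(m=0.15, theta=1.0, sigma=0.3, alpha_t=0.2, alpha_V=0.1, H=5.0)
    groups = tuple(
        GroupDesign(f"FI{d:g}", (Phase("acquisition", ((_fi("CS", d), 150),)),), params)
        for d in (5.0, 10.0, 20.0)
    )
    return ExperimentDesign(
        "isi_effect", groups, "150 reinforced trials at FI 5, 10 and 20 s"
    )


def _build_vi_vs_fi() -> ExperimentDesign:
    params = dict(m=0.2, theta=1.0, sigma=0.3, alpha_t=0.1, alpha_V=0.1, H=40.0)
    peak = _peak("CS", 135.0, 135.0)
    vi = GroupDesign(
        "VI30",
        (
            Phase(
                "training",
                ((VITrialTemplate("CS", 15, 45), 1500), (peak, 375)),
                shuffle=True,
            ),
        ),
        params,
    )
    fi = GroupDesign(
        "FI30",
        (Phase("training", ((_fi("CS", 30.0), 500), (peak, 125)), shuffle=True),),
        params,
    )
    return ExperimentDesign(
        "vi_vs_fi",
        (vi, fi),
        "variable interval U(15,45) s vs fixed interval 30 s, 135-s peak probes "
        "interleaved with probability 0.25",
    )


def _build_mixed_fi() -> ExperimentDesign:
    params = dict(m=0.2, theta=1.0, sigma=0.425, alpha_t=0.2, alpha_V=0.1, H=30.0)
    group = GroupDesign(
        "MFI15-75",
        (
            Phase(
                "training",
                ((_fi("A", 15.0), 200), (_fi("A", 75.0), 200)),
                shuffle=True,
            ),
        ),
        params,
        n_representations={"A": 2},
    )
    return ExperimentDesign(
        "mixed_fi", (group,), "one CS reinforced at 15 or 75 s (two timers)"
    )


def _build_latent_inhibition() -> ExperimentDesign:
    params = dict(
        m=0.2,
        theta=1.0,
        sigma=0.35,
        alpha_t=0.1,
        alpha_V=0.08,
        H=4.0,
        pearce_hall=True,
        ph_alpha_novel=0.4,
        ph_gamma=0.03,
        adaptive_width=True,
        sigma_init=0.6,
        sigma_target=0.35,
        alpha_sigma=0.025,
    )
    pre = GroupDesign(
        "preexposed",
        (
            Phase("preexposure", ((_ext("A", 5.0), 80),)),
            Phase("conditioning", ((_fi("A", 5.0), 250),)),
        ),
        params,
    )
    ctrl = GroupDesign(
        "control",
        (Phase("conditioning", ((_fi("C", 5.0), 250),)),),
        params,
    )
    return ExperimentDesign(
        "latent_inhibition",
        (pre, ctrl),
        "80 non-reinforced preexposures then 250 reinforced trials, vs "
        "non-preexposed control (Pearce-Hall rate, adaptive width)",
    )


def _blocking_compound(first: str, d1: float, second: str, d2: float) -> TrialSpec:
    """Co-terminating compound: the shorter CS starts late; US at the end."""
    t_end = max(d1, d2)
    stims = (
        _cs(first, d1, onset=t_end - d1),
        _cs(second, d2, onset=t_end - d2),
    )
    return TrialSpec(stims, "reinforced", t_end, us_time=t_end)


def _build_blocking() -> ExperimentDesign:
    params = dict(m=0.2, theta=1.0, sigma=0.35, alpha_t=0.2, alpha_V=0.1, H=10.0)
    groups = (
        GroupDesign(
            "blocking_15_10",  # 15-s pretrained A blocks 10-s B1
            (
                Phase("pretraining", ((_fi("A", 15.0), 120),)),
                Phase("compound", ((_blocking_compound("A", 15.0, "B1", 10.0), 60),)),
            ),
            params,
        ),
        GroupDesign(
            "control_15_10",  # novel 15-s C compounded with 10-s B2
            (Phase("compound", ((_blocking_compound("C", 15.0, "B2", 10.0), 60),)),),
            params,
        ),
        GroupDesign(
            "blocking_10_15",  # 10-s pretrained A fails to block 15-s B1
            (
                Phase("pretraining", ((_fi("A", 10.0), 120),)),
                Phase("compound", ((_blocking_compound("B1", 15.0, "A", 10.0), 60),)),
            ),
            params,
        ),
        GroupDesign(
            "control_10_15",
            (Phase("compound", ((_blocking_compound("B2", 15.0, "C", 10.0), 60),)),),
            params,
        ),
    )
    return ExperimentDesign(
        "blocking_durations",
        groups,
        "blocking with co-terminating CSs of unequal duration, both orders, "
        "with matched novel-CS controls",
    )


def _build_disinhibition_compound_peak() -> ExperimentDesign:
    params = dict(
        m=0.25,
        theta=1.0,
        sigma=0.18,
        alpha_t=0.75,
        alpha_V=0.1,
        H=5.0,
        compound_policy="faster_timer",
    )
    disinhibition = GroupDesign(
        "disinhibition",
        (
            Phase(
                "pretraining",
                ((_fi("A", 30.0), 100), (_ext("B", 30.0), 100)),
                shuffle=True,
            ),
            Phase(
                "compound",
                (
                    (_fi("A", 30.0), 300),
                    (_fi("B", 30.0), 300),
                    (_blocking_compound("A", 30.0, "B", 30.0), 100),
                ),
                shuffle=True,
            ),
        ),
        params,
    )
    compound_peak = GroupDesign(
        "compound_peak",
        (
            Phase(
                "pretraining",
                ((_fi("A", 50.0), 100), (_fi("B", 50.0), 100)),
                shuffle=True,
            ),
            Phase(
                "peak",
                (
                    (_fi("A", 50.0), 300),
                    (_fi("B", 50.0), 300),
                    (_peak(("A", "B"), 130.0, 130.0), 100),
                    (_peak("A", 130.0, 130.0), 50),
                    (_peak("B", 130.0, 130.0), 50),
                ),
                shuffle=True,
            ),
        ),
        params,
    )
    return ExperimentDesign(
        "disinhibition_compound_peak",
        (disinhibition, compound_peak),
        "FI-30 compound reinforcement (disinhibition of delay) and FI-50 "
        "compound peak procedure; responding follows the faster timer",
    )


def _build_conditioned_inhibition() -> ExperimentDesign:
    params = dict(m=0.16, theta=1.0, sigma=0.35, alpha_t=0.09, alpha_V=0.06, H=30.0)

    def ext_compound(exc: str, inh: str, dur: float) -> TrialSpec:
        return TrialSpec((_cs(exc, dur), _cs(inh, dur)), "extinction", dur)

    group = GroupDesign(
        "inhibition",
        (
            Phase(
                "discrimination",
                (
                    (_fi("E1", 10.0), 300),
                    (_fi("E2", 30.0), 300),
                    (ext_compound("E1", "I1", 10.0), 300),
                    (ext_compound("E2", "I2", 30.0), 300),
                ),
                shuffle=True,
            ),
            Phase(
                "transfer",
                ((_fi("E3", 10.0), 300), (_fi("E3", 30.0), 300)),
                shuffle=True,
            ),
            Phase(
                "summation_test",
                (
                    (_peak(("E3", "I1"), 90.0, 90.0), 100),
                    (_peak(("E3", "I2"), 90.0, 90.0), 100),
                    (_peak("E3", 90.0, 90.0), 100),
                ),
                shuffle=True,
            ),
        ),
        params,
        n_representations={"E3": 2},
    )
    return ExperimentDesign(
        "conditioned_inhibition",
        (group,),
        "inhibitors timing US omission at 10 or 30 s; summation test on a "
        "mixed-FI transfer excitor",
    )


def _build_temporal_averaging() -> ExperimentDesign:
    params = dict(
        m=0.2,
        theta=1.0,
        sigma=0.35,
        alpha_t=0.2,
        alpha_V=0.1,
        H=30.0,
        compound_policy="average",
    )
    long_cs = _cs("L", 20.0, modality="visual")
    short_cs = _cs("S", 10.0, modality="auditory")
    peak_dur = 60.0
    group = GroupDesign(
        "FI10-20",
        (
            Phase(
                "training",
                (
                    (TrialSpec((long_cs,), "reinforced", 20.0, us_time=20.0), 700),
                    (TrialSpec((short_cs,), "reinforced", 10.0, us_time=10.0), 700),
                    (_peak("L", peak_dur, peak_dur), 154),
                    (_peak("S", peak_dur, peak_dur), 154),
                    (_peak(("S", "L"), peak_dur, peak_dur), 154),
                ),
                shuffle=True,
            ),
        ),
        params,
    )
    return ExperimentDesign(
        "temporal_averaging",
        (group,),
        "cross-modal 10-s and 20-s CSs; compound probes pool half of each "
        "timer's rate (harmonic averaging)",
    )


_BUILDERS = {
    "acquisition_extinction_reacquisition": _build_acquisition,
    "extinction_duration_change": _build_extinction_duration_change,
    "isi_effect": _build_isi_effect,
    "vi_vs_fi": _build_vi_vs_fi,
    "mixed_fi": _build_mixed_fi,
    "latent_inhibition": _build_latent_inhibition,
    "blocking_durations": _build_blocking,
    "disinhibition_compound_peak": _build_disinhibition_compound_peak,
    "conditioned_inhibition": _build_conditioned_inhibition,
    "temporal_averaging": _build_temporal_averaging,
}

PRESET_NAMES = tuple(_BUILDERS)

_PARAM_KEYS = {
    "m",
    "theta",
    "sigma",
    "alpha_t",
    "alpha_V",
    "H",
    "dt_ms",
    "A_init",
    "noise_form",
    "compound_policy",
    "averaging_weighting",
    "pearce_hall",
    "ph_alpha_novel",
    "ph_gamma",
    "adaptive_width",
    "sigma_init",
    "sigma_target",
    "alpha_sigma",
    "psi_update_floor",
}


def build_design(
    name: str, overrides: Mapping[str, object] | None = None
) -> ExperimentDesign:
    """Build a named preset, optionally overriding parameters.

    Override keys are model-parameter names (applied to every group) plus
    ``n_trials``, which caps each trial block's count — handy for quick
    runs and fixtures.
    """
    if name not in _BUILDERS:
        raise UnknownDesignError(
            f"unknown design {name!r}; available presets: "
            + ", ".join(sorted(PRESET_NAMES))
        )
    design = _BUILDERS[name]()
    if not overrides:
        return design

    bad = set(overrides) - _PARAM_KEYS - {"n_trials"}
    if bad:
        raise ValueError(f"unknown override keys: {sorted(bad)}")

    n_trials = overrides.get("n_trials")
    param_over = {k: v for k, v in overrides.items() if k in _PARAM_KEYS}

    groups = []
    for g in design.groups:
        phases = g.phases
        if n_trials is not None:
            phases = tuple(
                replace(
                    ph,
                    blocks=tuple(
                        (t, min(c, int(n_trials))) for t, c in ph.blocks
                    ),
                )
                for ph in g.phases
            )
        groups.append(
            replace(g, phases=phases, params={**g.params, **param_over})
        )
    return replace(design, groups=tuple(groups))


def list_designs() -> dict[str, str]:
    """Catalogue of the preset names with one-line summaries."""
    out = {}
    for name, builder in _BUILDERS.items():
        d = builder()
        counts = "; ".join(
            f"{g.name}: " + " | ".join(f"{p.name} {p.n_trials}" for p in g.phases)
            for g in d.groups
        )
        out[name] = f"{d.description} [{counts}]"
    return out
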