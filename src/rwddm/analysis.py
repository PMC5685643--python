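"""Reduction of simulation traces to reported measures.

Trial-averaged response curves, peak-procedure statistics (peak time,
coefficient of variation), normalized-curve superimposition for timescale
invariance, acquisition speed (trials to criterion) and the first-window
extinction-rate reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationTrace

__all__ = [
    "ResponseCurve",
    "average_curve",
    "normalize_curve",
    "peak_time",
    "trials_to_criterion",
    "first_window_rate",
    "empirical_cv",
    "superimposition_rmse",
    "plot_curves",
]


@dataclass(frozen=True)
class ResponseCurve:
    """Mean CR against within-trial time (seconds)."""

    time_s: np.ndarray
    values: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        if len(self.time_s) != len(self.values):
            raise ValueError("time and value grids differ in length")


def _selected_indices(
    trace: SimulationTrace,
    trial_filter: Callable[[pd.Series], bool] | None,
    trial_type: str | None,
    stimuli,
    phase: str | None,
    last_n: int | None,
) -> list[int]:
    df = trace.select_trials(trial_type=trial_type, stimuli=stimuli, phase=phase)
    if trial_filter is not None:
        df = df[df.apply(trial_filter, axis=1)]
    idx = [i for i in df.index if i in trace.cr]
    if last_n is not None:
        idx = idx[-last_n:]
    return idx


def average_curve(
    trace: SimulationTrace,
    trial_filter: Callable[[pd.Series], bool] | None = None,
    *,
    trial_type: str | None = None,
    stimuli=None,
    phase: str | None = None,
    last_n: int | None = None,
) -> ResponseCurve:
    """Pointwise mean CR over the selected (recorded) trials.

    Selected trials must share a duration; raises on an empty selection.
    """
    idx = _selected_indices(trace, trial_filter, trial_type, stimuli, phase, last_n)
    if not idx:
        raise ValueError("no recorded trials match the filter")
    lengths = {len(trace.cr[i]) for i in idx}
    if len(lengths) != 1:
        raise ValueError(f"selected trials have unequal lengths: {sorted(lengths)}")
    mat = np.stack([trace.cr[i] for i in idx]).astype(float)
    n = lengths.pop()
    time_s = (np.arange(1, n + 1) * trace.dt_ms) / 1000.0
    return ResponseCurve(time_s=time_s, values=mat.mean(axis=0), n_trials=len(idx))


def normalize_curve(curve: ResponseCurve, reference_time: float) -> ResponseCurve:
    """Proportion-of-maximum response against proportion-of-reference time."""
    if not reference_time > 0:
        raise ValueError("reference_time must be > 0")
    peak = float(np.max(curve.values))
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero curve")
    return ResponseCurve(
        time_s=curve.time_s / reference_time,
        values=curve.values / peak,
        n_trials=curve.n_trials,
    )


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="same")


def peak_time(curve: ResponseCurve, smoothing_window_s: float = 1.0) -> float:
    """Time of the (smoothed) maximum; ties resolve to the earliest time.

    Raw stochastic curves are jagged, so a moving-average smoother
    (default 1 s) is applied before the argmax.
    """
    if len(curve.values) == 0:
        raise ValueError("empty curve")
    dt_s = float(curve.time_s[1] - curve.time_s[0]) if len(curve.time_s) > 1 else 1.0
    window = max(int(round(smoothing_window_s / dt_s)), 1)
    sm = _smooth(curve.values, window)
    return float(curve.time_s[int(np.argmax(sm))])


def trials_to_criterion(
    v_series: Sequence[float],
    criterion: float = 0.5,
    v_asymptote: float | None = None,
) -> int | None:
    """First trial (1-based) at which V reaches ``criterion`` of asymptote.

    The asymptote defaults to the mean of the final 10 values.  Returns
    ``None`` if the criterion is never reached.
    """
    v = np.asarray(v_series, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    target = criterion * (
        v_asymptote if v_asymptote is not None else float(np.mean(v[-10:]))
    )
    hits = np.nonzero(v >= target)[0]
    return int(hits[0]) + 1 if hits.size else None


def first_window_rate(
    trace: SimulationTrace,
    window_s: float = 10.0,
    pair_average: bool = True,
    scale_divisor: float = 100.0,
    *,
    trial_type: str | None = None,
    phase: str | None = None,
) -> np.ndarray:
    """Windowed extinction-rate series: per-trial CR summed over the first
    ``window_s`` seconds, adjacent trials averaged two by two, rescaled.

    With an odd trial count the final unpaired trial is dropped.
    """
    idx = _selected_indices(trace, None, trial_type, None, phase, None)
    if not idx:
        raise ValueError("no recorded trials match the filter")
    w = int(round(window_s * 1000.0 / trace.dt_ms))
    sums = np.array([float(np.sum(trace.cr[i][:w])) for i in idx])
    if pair_average:
        n_pairs = len(sums) // 2
        sums = sums[: 2 * n_pairs].reshape(n_pairs, 2).mean(axis=1)
    return sums / scale_divisor


def empirical_cv(values: Sequence[float]) -> float:
    """Coefficient of variation: population SD divided by the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    mean = float(np.mean(v))
    if mean == 0.0:
        raise ValueError("mean is zero; CV undefined")
    return float(np.std(v) / mean)


def superimposition_rmse(
    curve_a: ResponseCurve,
    curve_b: ResponseCurve,
    reference_a: float,
    reference_b: float,
    n_grid: int = 100,
    rel_max: float | None = None,
) -> float:
    """RMSE between two normalized curves on a common relative-time grid.

    Quantifies how well the curves superimpose after scaling each by its
    own reference time (timescale invariance predicts a small value).
    The grid spans (0, rel_max]; by default the largest relative time
    covered by both curves.
    """
    na = normalize_curve(curve_a, reference_a)
    nb = normalize_curve(curve_b, reference_b)
    top = min(na.time_s[-1], nb.time_s[-1])
    if rel_max is not None:
        top = min(top, rel_max)
    grid = np.linspace(top / n_grid, top, n_grid)
    ya = np.interp(grid, na.time_s, na.values)
    yb = np.interp(grid, nb.time_s, nb.values)
    return float(math.sqrt(np.mean((ya - yb) ** 2)))


def plot_curves(curves: dict[str, ResponseCurve], path, title: str = "",
                xlabel: str = "time (s)", ylabel: str = "response strength"):
    """Render averaged response curves to ``path`` (static panel)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, c in curves.items():
        ax.plot(c.time_s, c.values, label=name)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
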