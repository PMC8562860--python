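"""Post-processing of simulated paths and exact-error landscapes.

Stationary histograms are time-weighted occupancies pooled over the
post-burn-in segments of one or more paths; oscillation periods come
from peak-to-peak differences after moving-average smoothing; the
validity landscapes tabulate, per (total, K_d) cell, the worst-case
relative error of an estimator over a partner-total scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from stoqssa.policy import max_error_over_partner
from stoqssa.ssa import Trajectory

__all__ = [
    "ErrorGrid",
    "error_grid",
    "stationary_histogram",
    "peak_to_peak_periods",
    "mode_occupancy",
    "total_variation",
    "ensemble_summary",
]


@dataclass
class ErrorGrid:
    """Worst-case relative-error landscape of one estimator.

    ``values[i, j]`` is the maximum relative error against the exact
    stationary mean at ``totals[i]``, ``kds[j]``, maximized over the
    partner-total scan.
    """

    totals: np.ndarray
    kds: np.ndarray
    values: np.ndarray
    method: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.totals) <= 0) or np.any(np.diff(self.kds) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("error-grid cells must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (total, K_d, total_Kd, max_relative_error)."""
        rows = [
            (int(t), kd, int(t) * kd, self.values[i, j])
            for i, t in enumerate(self.totals)
            for j, kd in enumerate(self.kds)
        ]
        return pd.DataFrame(
            rows, columns=["total", "K_d", "total_Kd", "max_relative_error"]
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.insert(0, "method", self.method)
        df.to_csv(path, sep="\t", index=False)


def error_grid(method, totals, kds) -> ErrorGrid:
    """Scan the worst-case relative error over a (total, K_d) grid.

    ``method`` is ``"stqssa"`` or ``("slqssa", k)``; each cell maximizes
    the relative error against the exact stationary mean over the partner
    grid of :func:`stoqssa.policy.max_error_over_partner`.
    """
    totals = np.asarray(sorted(int(t) for t in totals))
    kds = np.asarray(sorted(float(k) for k in kds))
    vals = np.empty((len(totals), len(kds)))
    for i, t in enumerate(totals):
        for j, kd in enumerate(kds):
            vals[i, j] = max_error_over_partner(int(t), float(kd), method)
    tag = method if isinstance(method, str) else f"{method[0]}:{method[1]}"
    return ErrorGrid(totals, kds, vals, tag)


def _occupancy(traj: Trajectory, species: str, burn_in: float):
    """Time-weighted (count, weight) arrays for one path after burn-in."""
    t, x = traj.times, traj.series(species)
    t_end = t[-1]
    if burn_in >= t_end:
        raise ValueError(f"burn_in {burn_in} >= path end {t_end}")
    # right-continuous steps: x[i] holds on [t[i], t[i+1])
    ends = np.append(t[1:], t_end)
    dur = np.clip(ends - np.maximum(t, burn_in), 0.0, None)
    return x, dur


def stationary_histogram(
    trajectories: Trajectory | list[Trajectory],
    species: str,
    burn_in: float | None = None,
) -> pd.Series:
    """Time-weighted stationary occupancy of a species, pooled over paths.

    ``burn_in`` (in time units) defaults to the first 20% of the horizon.
    Returns a probability Series indexed by integer count, summing to 1.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise ValueError("no trajectories given")
    acc: dict[int, float] = {}
    for tr in trajectories:
        b = 0.2 * tr.times[-1] if burn_in is None else burn_in
        x, w = _occupancy(tr, species, b)
        for xi, wi in zip(x.tolist(), w.tolist()):
            if wi > 0.0:
                acc[xi] = acc.get(xi, 0.0) + wi
    total = sum(acc.values())
    if total <= 0:
        raise ValueError("empty post-burn-in window")
    s = pd.Series(acc).sort_index()
    return s / total


def total_variation(p: pd.Series, q: pd.Series) -> float:
    """Total-variation distance between two probability tables."""
    idx = p.index.union(q.index)
    return 0.5 * float(
        (p.reindex(idx, fill_value=0.0) - q.reindex(idx, fill_value=0.0))
        .abs()
        .sum()
    )


def peak_to_peak_periods(
    trajectory: Trajectory,
    species: str,
    smooth_window: float = 2.0,
    min_prominence: float | None = None,
    min_separation: float | None = None,
) -> np.ndarray:
    """Successive peak-to-peak time differences of an oscillatory species.

    The series is smoothed with a moving average of width
    ``smooth_window`` (time units), then peaks are detected with a
    prominence filter (default: 25% of the signal's interquartile range)
    and a minimum-separation filter (default: half the dominant
    autocorrelation lag).  Returns an empty array (no periods) when
    fewer than two peaks survive.
    """
    t, x = trajectory.times, trajectory.series(species).astype(float)
    if len(t) < 4:
        return np.empty(0)
    dt = float(np.median(np.diff(t)))
    win = max(1, int(round(smooth_window / dt)))
    kernel = np.ones(win) / win
    xs = np.convolve(x, kernel, mode="same")
    if min_prominence is None:
        q75, q25 = np.percentile(xs, [75, 25])
        min_prominence = 0.25 * (q75 - q25)
        if min_prominence <= 0:
            min_prominence = 0.25 * (xs.max() - xs.min() + 1e-12)
    if min_separation is None:
        min_separation = 0.5 * _dominant_lag(xs, dt)
    distance = max(1, int(round(min_separation / dt)))
    peaks, _ = find_peaks(xs, prominence=min_prominence, distance=distance)
    if len(peaks) < 2:
        return np.empty(0)
    return np.diff(t[peaks])


def _dominant_lag(x: np.ndarray, dt: float) -> float:
    """First non-trivial autocorrelation maximum, in time units."""
    x = x - x.mean()
    n = len(x)
    ac = np.correlate(x, x, mode="full")[n - 1 :]
    if ac[0] <= 0:
        return dt
    ac /= ac[0]
    # first local max after the zero-lag peak has decayed
    below = np.nonzero(ac < 0)[0]
    start = below[0] if len(below) else 1
    rest = ac[start:]
    if len(rest) < 3:
        return dt * max(1, n // 4)
    lag = start + int(np.argmax(rest))
    return dt * max(lag, 1)


def mode_occupancy(histogram: pd.Series, boundary: float) -> float:
    """Probability mass strictly above ``boundary`` in a count histogram."""
    return float(histogram[histogram.index > boundary].sum())


def ensemble_summary(trajectories: list[Trajectory], species=None) -> pd.DataFrame:
    """Per-time mean and standard deviation across grid-recorded paths."""
    if not trajectories:
        raise ValueError("no trajectories")
    t0 = trajectories[0]
    if any(tr.recording_mode != "grid" for tr in trajectories):
        raise ValueError("ensemble summaries need grid-recorded paths")
    species = species or t0.species
    out = {"time": t0.times}
    stack = np.stack([tr.states for tr in trajectories])  # (paths, times, species)
    for s in species:
        j = t0.species.index(s)
        out[f"{s}_mean"] = stack[:, :, j].mean(axis=0)
        out[f"{s}_sd"] = stack[:, :, j].std(axis=0, ddof=1) if len(
            trajectories
        ) > 1 else np.zeros(len(t0.times))
    return pd.DataFrame(out)
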