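"""Equilibration detection from RMSD series and pooled post-equilibration stats.

An ensemble is judged equilibrated once its RMSD-vs-time curve flattens.
Published trajectory studies typically choose the equilibration point by
eye; here an explicit windowed-stability criterion makes the choice
reproducible: the series is cut into non-overlapping windows and the
equilibration time is the earliest window boundary from which every later
window mean stays within a tolerance of the final window mean (and no
window-to-window mean rise exceeds that tolerance).  A stable tail of at
least two windows is required, so a series that never settles is reported
as not equilibrated rather than as equilibrating at the very end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mptraj.geometry import SeriesStats

__all__ = [
    "EquilibrationResult",
    "detect_equilibration",
    "pooled_equilibrated_time",
    "post_equilibration_stats",
    "pooled_post_equilibration_stats",
]


@dataclass
class EquilibrationResult:
    equilibrated: bool
    t_eq_ns: float | None                 # None iff not equilibrated
    equilibrated_frames: np.ndarray       # frame positions with time >= t_eq
    stats: SeriesStats | None


def detect_equilibration(series: pd.Series, window_ns: float = 25.0,
                         tol_A: float = 0.5) -> EquilibrationResult:
    """Locate the equilibration point of an RMSD time series.

    ``series`` must be indexed by time in nanoseconds.  The reported
    equilibration time is snapped up to a whole window boundary (measured
    from the first time point).  Larger tolerances can only move the
    detected point earlier.
    """
    if window_ns <= 0 or tol_A < 0:
        raise ValueError("window_ns must be positive and tol_A non-negative")
    times = np.asarray(series.index, dtype=float)
    values = np.asarray(series.values, dtype=float)
    t0 = times[0]
    span = times[-1] - t0
    n_windows = int(span // window_ns)
    if n_windows < 2:
        raise ValueError("series must cover at least two windows")
    which = np.floor((times - t0) / window_ns).astype(int)
    in_range = which < n_windows
    means = np.array([
        values[in_range & (which == w)].mean() for w in range(n_windows)
    ])
    final = means[-1]
    chosen = None
    for w in range(n_windows - 1):
        tail = means[w:]
        if np.all(np.abs(tail - final) <= tol_A) and np.all(np.diff(tail) <= tol_A):
            chosen = w
            break
    if chosen is None:
        return EquilibrationResult(False, None, np.array([], dtype=int), None)
    t_eq = t0 + chosen * window_ns
    frames = np.flatnonzero(times >= t_eq)
    stats = SeriesStats.from_values(values[frames])
    return EquilibrationResult(True, float(t_eq), frames, stats)


def pooled_equilibrated_time(run_lengths_ns, t_eqs_ns) -> float:
    """Total post-equilibration time pooled over runs, in microseconds.

    Reported to one decimal place, matching the convention of quoting
    pooled trajectory lengths like "2.7 us".
    """
    lengths = np.asarray(run_lengths_ns, dtype=float)
    t_eqs = np.asarray(t_eqs_ns, dtype=float)
    if lengths.shape != t_eqs.shape:
        raise ValueError("run_lengths_ns and t_eqs_ns must have equal length")
    if np.any(t_eqs > lengths):
        raise ValueError("equilibration point exceeds run length")
    if np.any(t_eqs < 0):
        raise ValueError("negative equilibration time")
    return round(float((lengths - t_eqs).sum()) / 1000.0, 1)


def post_equilibration_stats(series: pd.Series,
                             result: EquilibrationResult) -> SeriesStats:
    """Ave/SD/Min/Max of the series over its equilibrated range."""
    if not result.equilibrated or len(result.equilibrated_frames) == 0:
        raise ValueError("no equilibrated frames to summarise")
    return SeriesStats.from_values(
        np.asarray(series.values, dtype=float)[result.equilibrated_frames])


def pooled_post_equilibration_stats(pairs) -> SeriesStats:
    """Pooled stats over (series, EquilibrationResult) pairs from several runs.

    Values are concatenated across runs before summarising, so the result
    is invariant to run order.
    """
    pooled: list[np.ndarray] = []
    for series, result in pairs:
        if not result.equilibrated:
            continue
        pooled.append(np.asarray(series.values, dtype=float)[result.equilibrated_frames])
    if not pooled:
        raise ValueError("no equilibrated runs to pool")
    return SeriesStats.from_values(np.concatenate(pooled))
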