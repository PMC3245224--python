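"""Cycle detection and episode assembly for pseudoperiodic series.

A *cycle* is the stretch of the series between two consecutive interior
local minima; cycles tile the segmented region without gap or overlap.
An *episode* is a block of ``m`` consecutive cycles and becomes one node of
the episode network.  Segmenting at local minima follows the convention of
cycle-network analysis of pseudoperiodic signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import TimeSeries
from .exceptions import NoCycleError

__all__ = ["Cycle", "Episode", "detect_cycles", "build_episodes"]


@dataclass(frozen=True)
class Cycle:
    """One oscillation: the half-open sample interval [start, end)."""

    start: int
    end: int
    values: np.ndarray

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Episode:
    """``m`` consecutive cycles, concatenated; a network node.

    ``cycle_span`` holds the (first, last) cycle ordinals, inclusive.
    """

    index: int
    cycle_span: tuple
    values: np.ndarray

    def __len__(self) -> int:
        return self.values.size


def _as_values(series) -> np.ndarray:
    if isinstance(series, TimeSeries):
        return series.values
    return np.asarray(series, dtype=float).ravel()


def detect_cycles(series, min_len: int = 5) -> list[Cycle]:
    """Segment a series into cycles at interior local minima.

    A boundary is an index ``t`` with ``x[t] < x[t-1]`` and ``x[t] <= x[t+1]``
    (plateau minima take the leftmost index).  Minima closer than ``min_len``
    samples to the previously retained boundary are suppressed, keeping the
    deeper of the two.  Samples before the first and after the last retained
    boundary belong to incomplete cycles and are discarded.

    Parameters
    ----------
    series : TimeSeries or array_like
        The input signal; at least 3 samples.
    min_len : int
        Minimum cycle length in samples; suppresses noise-induced minima.

    Returns
    -------
    list of Cycle, in temporal order.

    Raises
    ------
    NoCycleError
        If fewer than two boundaries survive (no complete cycle).
    """
    x = _as_values(series)
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if x.size < 3:
        raise NoCycleError("series too short to contain a cycle (need >= 3 samples)")

    interior = np.nonzero((x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:]))[0] + 1
    kept: list[int] = []
    for t in interior:
        if kept and t - kept[-1] < min_len:
            if x[t] < x[kept[-1]]:
                kept[-1] = int(t)  # moving right: spacing to earlier boundaries grows
        else:
            kept.append(int(t))
    if len(kept) < 2:
        raise NoCycleError("no complete cycle found (fewer than 2 boundaries)")
    return [Cycle(a, b, x[a:b]) for a, b in zip(kept[:-1], kept[1:])]


def build_episodes(cycles: list[Cycle], m: int) -> list[Episode]:
    """Group cycles into ``floor(n_C / m)`` non-overlapping episodes.

    Episodes are blocks of ``m`` consecutive cycles in series order; the
    trailing ``n_C mod m`` cycles are discarded.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    n_c = len(cycles)
    if m > n_c:
        raise ValueError(f"m={m} exceeds the number of cycles ({n_c})")
    n_e = n_c // m
    episodes = []
    for j in range(n_e):
        block = cycles[j * m:(j + 1) * m]
        values = np.concatenate([c.values for c in block])
        episodes.append(Episode(j, (j * m, (j + 1) * m - 1), values))
    return episodes
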