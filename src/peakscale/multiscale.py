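"""Scale-space decomposition of the corrected read-depth signal.

The signal is smoothed with sliding-window medians at a geometric series
of window lengths.  At each scale, candidate enriched regions are the
stretches between consecutive local minima of the smoothed signal; a
candidate whose smoothed peak retains too small a fraction of the raw peak
(the over-smoothing statistic) is discarded.

Median filtering is non-linear: a rectangular enrichment of width w
survives smoothing for window lengths below about 2w and is attenuated
above, which is what makes the window length an interpretable length
scale.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _filters
from .signal_io import GenomicInterval, SignalProfile

__all__ = [
    "ScaleSchedule",
    "ScaleDecomposition",
    "CandidateER",
    "make_schedule",
    "median_filter",
    "decompose",
    "find_extrema",
    "candidate_ers",
    "filter_oversmoothed",
]

DEFAULT_SIGMA = 1.5
DEFAULT_GAMMA = 4.0


@dataclass(frozen=True)
class ScaleSchedule:
    """Geometric series of median-filter window lengths."""

    l_start: int
    l_end: int
    sigma: float
    windows: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class ScaleDecomposition:
    """Stack of median-smoothed profiles, one per window length."""

    schedule: ScaleSchedule
    smoothed: list[SignalProfile]


@dataclass(frozen=True)
class CandidateER:
    """A between-minima region of one smoothed scale, before trimming."""

    interval: GenomicInterval
    scale_index: int
    max_smoothed: float
    max_raw: float


def make_schedule(
    l_start: int, l_end: int, sigma: float = DEFAULT_SIGMA
) -> ScaleSchedule:
    """Window lengths ``floor(l_start * sigma**k)`` for k = 0, 1, ... <= l_end.

    Duplicate lengths (possible for very small ``l_start``) are collapsed.
    """
    if l_start <= 0:
        raise ValueError("l_start must be positive")
    if l_end < l_start:
        raise ValueError("l_end must be >= l_start")
    if sigma <= 1:
        raise ValueError("sigma must be > 1")
    windows: list[int] = []
    k = 0
    while True:
        w = math.floor(l_start * sigma**k)
        if w > l_end:
            break
        if not windows or w != windows[-1]:
            windows.append(w)
        k += 1
    return ScaleSchedule(l_start=l_start, l_end=l_end, sigma=sigma, windows=tuple(windows))


def median_filter(profile: SignalProfile, window: int) -> SignalProfile:
    """Sliding-window median with the histogram-update algorithm.

    The window at position i spans ``[i - window//2, i + window//2]``
    inclusive (truncated at the chromosome ends); output equals a naive
    per-position sort-based median taking the lower middle element for
    even-sized (truncated) windows.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    smoothed = _filters.sliding_median(profile.values, window // 2)
    return SignalProfile(profile.chrom, smoothed)


def decompose(profile: SignalProfile, schedule: ScaleSchedule) -> ScaleDecomposition:
    """One independent median-filter pass per window length (not cascaded)."""
    smoothed = [median_filter(profile, w) for w in schedule.windows]
    return ScaleDecomposition(schedule=schedule, smoothed=smoothed)


def find_extrema(values: np.ndarray | SignalProfile) -> tuple[np.ndarray, np.ndarray]:
    """Interior local minima and maxima from derivative sign changes.

    The derivative is the difference of consecutive values; an extremum is
    placed where the sign of the nearest preceding nonzero derivative
    flips, at the first position of the flat run (plateau) it terminates.
    Chromosome boundaries are not reported here; region construction
    treats them as implicit minima.
    """
    if isinstance(values, SignalProfile):
        values = values.values
    x = np.asarray(values)
    n = x.size
    if n < 3:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    d = np.diff(x)
    nz = np.flatnonzero(d)
    if nz.size < 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    s = np.sign(d[nz])
    flips = np.flatnonzero(s[1:] != s[:-1]) + 1
    positions = nz[flips - 1] + 1  # first position of the terminating plateau
    rising = s[flips] > 0
    minima = positions[rising].astype(np.int64)
    maxima = positions[~rising].astype(np.int64)
    return minima, maxima


def candidate_ers(
    decomp: ScaleDecomposition, raw: SignalProfile
) -> list[list[CandidateER]]:
    """Between-minima candidate regions for every scale.

    *raw* is the mappability-corrected, unsmoothed profile; each candidate
    records the smoothed and raw signal maxima over its interval.
    Chromosome start and end act as implicit minima so terminal
    enrichments are kept; candidates whose smoothed maximum is zero (flat
    background) are dropped.
    """
    out: list[list[CandidateER]] = []
    raw_values = raw.values
    n = len(raw)
    for scale_index, smoothed in enumerate(decomp.smoothed):
        sm = smoothed.values
        if len(smoothed) != n:
            raise ValueError("smoothed and raw profiles differ in length")
        minima, _ = find_extrema(sm)
        bounds = np.unique(np.concatenate(([0], minima, [n])))
        if bounds.size < 2 or n == 0:
            out.append([])
            continue
        starts = bounds[:-1]
        ends = bounds[1:]
        max_sm = np.maximum.reduceat(sm, starts)
        max_raw = np.maximum.reduceat(raw_values, starts)
        scale_out = [
            CandidateER(
                interval=GenomicInterval(raw.chrom, int(s), int(e)),
                scale_index=scale_index,
                max_smoothed=float(ms),
                max_raw=float(mr),
            )
            for s, e, ms, mr in zip(starts, ends, max_sm, max_raw)
            if ms > 0
        ]
        out.append(scale_out)
    return out


def filter_oversmoothed(
    candidates: list[CandidateER], gamma: float = DEFAULT_GAMMA
) -> list[CandidateER]:
    """Drop candidates whose raw peak was smoothed away.

    The smoothing statistic is ``max_raw / max_smoothed`` (>= 1 for median
    filtering); a candidate is discarded when it exceeds *gamma*, i.e. the
    smoothed peak retains less than 1/gamma of the raw peak.  A zero
    smoothed maximum with positive raw maximum counts as infinite and is
    discarded.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    kept = []
    for cand in candidates:
        if cand.max_smoothed <= 0:
            continue
        if cand.max_raw / cand.max_smoothed > gamma:
            continue
        kept.append(cand)
    return kept
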