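"""Scale-specific enriched regions (SSERs).

Candidate regions from the multiscale decomposition are trimmed against a
per-megabase Poisson background (dropping everything below the 5%
false-positive threshold of the local window) and then tested for ChIP
enrichment over the normalized control with a one-tailed binomial test.
Candidates surviving both steps at a given smoothing scale are that
scale's SSERs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .er_calls import binomial_pvalue
from .multiscale import (
    CandidateER,
    ScaleDecomposition,
    candidate_ers,
    filter_oversmoothed,
)
from .preprocess import FragmentIndex
from .signal_io import GenomicInterval, SignalProfile

logger = logging.getLogger(__name__)

__all__ = [
    "PoissonBackground",
    "SSER",
    "poisson_threshold",
    "fit_background",
    "trim_poisson",
    "sser_significance",
    "call_ssers",
]

DEFAULT_BACKGROUND_WINDOW = 1_000_000
SSER_P_CUTOFF = 0.05


@dataclass
class PoissonBackground:
    """Per-window Poisson background: mean signal and its 5%-FPR threshold."""

    window_length: int
    mu: np.ndarray
    tau: np.ndarray

    def tau_per_position(self, n: int) -> np.ndarray:
        """Threshold value applying to each of the first *n* positions."""
        return np.repeat(self.tau, self.window_length)[:n]


@dataclass(frozen=True)
class SSER:
    """A significant enriched region specific to one smoothing scale."""

    interval: GenomicInterval
    scale_index: int
    p_value: float
    chip_count: int
    control_count: int


def poisson_threshold(mu) -> np.ndarray | int:
    """Smallest non-negative integer t with Poisson(mu) CDF strictly > 0.95."""
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=np.float64))
    if mu_arr.size and mu_arr.min() < 0:
        raise ValueError("mu must be non-negative")
    # ppf gives the smallest t with CDF >= 0.95; bump ties up to strict.
    t = poisson.ppf(0.95, mu_arr)
    t = np.where(np.isfinite(t), t, 0).astype(np.int64)
    needs_bump = poisson.cdf(t, mu_arr) <= 0.95
    while np.any(needs_bump):
        t = np.where(needs_bump, t + 1, t)
        needs_bump = poisson.cdf(t, mu_arr) <= 0.95
    if np.isscalar(mu) or np.asarray(mu).ndim == 0:
        return int(t[0])
    return t


def fit_background(
    profile: SignalProfile, window_length: int = DEFAULT_BACKGROUND_WINDOW
) -> PoissonBackground:
    """Mean signal per genome window, zeros included; trailing partial
    windows use their actual length."""
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    v = profile.values.astype(np.float64)
    n = v.size
    if n == 0:
        return PoissonBackground(window_length, np.zeros(0), np.zeros(0, dtype=np.int64))
    edges = np.arange(0, n, window_length)
    sums = np.add.reduceat(v, edges)
    sizes = np.minimum(edges + window_length, n) - edges
    mu = sums / sizes
    tau = np.atleast_1d(poisson_threshold(mu))
    return PoissonBackground(window_length=window_length, mu=mu, tau=tau)


def _trim_batch(
    starts: np.ndarray,
    ends: np.ndarray,
    raw: np.ndarray,
    bg: PoissonBackground,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Poisson trimming: first/last above-threshold positions.

    Returns (new_starts, new_ends, keep_mask); entries with no position
    above the local threshold are flagged for removal.
    """
    tau_pos = bg.tau_per_position(raw.size)
    above = np.flatnonzero(raw > tau_pos)
    if above.size == 0:
        keep = np.zeros(starts.size, dtype=bool)
        return starts, ends, keep
    first_idx = np.searchsorted(above, starts, side="left")
    last_idx = np.searchsorted(above, ends, side="left") - 1
    keep = (first_idx < above.size) & (first_idx <= last_idx)
    new_starts = np.where(keep, above[np.minimum(first_idx, above.size - 1)], starts)
    new_ends = np.where(keep, above[np.maximum(last_idx, 0)] + 1, ends)
    return new_starts, new_ends, keep


def trim_poisson(
    candidate: CandidateER | GenomicInterval,
    raw: SignalProfile,
    bg: PoissonBackground,
) -> GenomicInterval | None:
    """Shrink a candidate to its first..last position strictly above the
    Poisson threshold of the covering background window; None if nothing
    in the candidate exceeds the threshold."""
    iv = candidate.interval if isinstance(candidate, CandidateER) else candidate
    if iv.start < 0 or iv.end > len(raw):
        raise ValueError("candidate interval outside the profile")
    s, e, keep = _trim_batch(
        np.asarray([iv.start]), np.asarray([iv.end]), raw.values, bg
    )
    if not keep[0]:
        return None
    return GenomicInterval(iv.chrom, int(s[0]), int(e[0]))


def sser_significance(
    trimmed: GenomicInterval,
    chip_reads: FragmentIndex,
    control_reads: FragmentIndex,
    rho: float,
    l_pval: int,
    scale_index: int = 0,
    p_cutoff: float = SSER_P_CUTOFF,
) -> SSER | None:
    """Binomial enrichment test of a trimmed region; None if p > cutoff.

    Counts are fragments overlapping the interval; the control count is
    scaled by the normalization factor *rho* inside the test.
    """
    if l_pval <= 0:
        raise ValueError("l_pval must be positive")
    n_chip = chip_reads.count(trimmed.start, trimmed.end)
    n_control = control_reads.count(trimmed.start, trimmed.end)
    length = len(trimmed)
    # The test window never exceeds the region itself, so normalization
    # only scales counts down; upscaling short regions would manufacture
    # significance out of depth-level noise.
    p = binomial_pvalue(n_chip, rho * n_control, length, length, min(l_pval, length))
    if p > p_cutoff:
        return None
    return SSER(
        interval=trimmed,
        scale_index=scale_index,
        p_value=float(p),
        chip_count=int(n_chip),
        control_count=int(n_control),
    )


def call_ssers(
    decomp: ScaleDecomposition,
    raw: SignalProfile,
    bg: PoissonBackground,
    chip_reads: FragmentIndex,
    control_reads: FragmentIndex,
    rho: float,
    l_pval: int,
    gamma: float = 4.0,
    p_cutoff: float = SSER_P_CUTOFF,
) -> tuple[list[SSER], dict[str, int]]:
    """Candidate regions -> over-smoothing filter -> Poisson trimming ->
    binomial significance, for every scale of one chromosome.

    Returns the SSER list and per-stage region counts for auditing.
    """
    counts = {"candidates": 0, "gamma_kept": 0, "trimmed": 0, "ssers": 0}
    ssers: list[SSER] = []
    per_scale = candidate_ers(decomp, raw)
    for scale_index, cands in enumerate(per_scale):
        counts["candidates"] += len(cands)
        kept = filter_oversmoothed(cands, gamma)
        counts["gamma_kept"] += len(kept)
        if not kept:
            continue
        starts = np.asarray([c.interval.start for c in kept], dtype=np.int64)
        ends = np.asarray([c.interval.end for c in kept], dtype=np.int64)
        # Trim against the smoothed profile of this scale: it is the
        # scale-s estimate of local enrichment, so the threshold crossing
        # marks where enrichment at this length scale ends.  Trimming on
        # the unsmoothed profile instead selects base-pair noise islands
        # (5% of background positions clear tau by construction), which
        # biases every downstream test.
        scale_values = decomp.smoothed[scale_index].values
        new_starts, new_ends, keep_mask = _trim_batch(starts, ends, scale_values, bg)
        new_starts = new_starts[keep_mask]
        new_ends = new_ends[keep_mask]
        counts["trimmed"] += int(keep_mask.sum())
        if new_starts.size == 0:
            continue
        n_chip = chip_reads.count_many(new_starts, new_ends)
        n_ctrl = control_reads.count_many(new_starts, new_ends)
        lengths = new_ends - new_starts
        # test window capped at the region's own length (see sser_significance)
        p = binomial_pvalue(
            n_chip, rho * n_ctrl, lengths, lengths, np.minimum(l_pval, lengths)
        )
        significant = p <= p_cutoff
        for s, e, pv, nc, nk in zip(
            new_starts[significant],
            new_ends[significant],
            np.atleast_1d(p)[significant],
            n_chip[significant],
            n_ctrl[significant],
        ):
            ssers.append(
                SSER(
                    interval=GenomicInterval(raw.chrom, int(s), int(e)),
                    scale_index=scale_index,
                    p_value=float(pv),
                    chip_count=int(nc),
                    control_count=int(nk),
                )
            )
    counts["ssers"] = len(ssers)
    return ssers, counts
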