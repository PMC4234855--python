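"""Final enriched-region calling.

SSERs from all smoothing scales are merged into maximal intervals, region
ends are refined by binomial P-value minimization, regions with strongly
strand-imbalanced signal are removed, and the survivors are scored with a
one-tailed binomial test against the normalized control and thresholded
on Benjamini-Hochberg q-values.  Each reported region carries a summit
(position of maximal corrected signal), optionally a trough (the signal
minimum between the two tallest peaks, reported only where mappability
rules out an artifactual dip), and its maximum SSER pileup scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom

from .mappability import MultiMappabilityProfile
from .multiscale import find_extrema
from .preprocess import FragmentIndex, RDProfiles
from .signal_io import GenomicInterval, SignalProfile

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichedRegion",
    "merge_ssers",
    "trim_pvalue_min",
    "strand_concordance_filter",
    "binomial_pvalue",
    "bh_qvalues",
    "find_summit",
    "find_trough",
    "call_ers",
]

DEFAULT_Q_CUTOFF = 0.05
DEFAULT_TROUGH_WINDOW = 50


@dataclass
class EnrichedRegion:
    interval: GenomicInterval
    p_value: float
    q_value: float
    chip_count: int
    control_count_normalized: float
    summit: int
    trough: int | None = None
    max_pileup_scale: int = 0


def merge_ssers(ssers) -> list[GenomicInterval]:
    """Union of SSER intervals: overlapping or book-ended intervals are
    coalesced into maximal intervals, sorted by (chrom, start)."""
    intervals = [s.interval if hasattr(s, "interval") else s for s in ssers]
    if not intervals:
        return []
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur = intervals[0]
    for iv in intervals[1:]:
        if iv.chrom == cur.chrom and iv.start <= cur.end:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
        else:
            merged.append(cur)
            cur = iv
    merged.append(cur)
    return merged


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(np.int64)


def binomial_pvalue(
    n_chip,
    n_control,
    l_chip,
    l_control,
    l_pval,
    inclusive: bool = False,
):
    """One-tailed binomial enrichment P-value on length-normalized counts.

    Counts are rescaled to a common window: ``n' = round(n / l * l_pval)``
    (half-up).  With N = n'_chip + n'_control, the P-value is the upper
    binomial(N, 1/2) tail strictly above n'_chip; ``inclusive=True``
    switches to P[X >= n'_chip].  Both normalized counts zero gives 1.
    Scalar inputs give a float; array inputs broadcast.
    """
    n_chip_arr = np.atleast_1d(np.asarray(n_chip, dtype=np.float64))
    n_control_arr = np.atleast_1d(np.asarray(n_control, dtype=np.float64))
    if (n_chip_arr < 0).any() or (n_control_arr < 0).any():
        raise ValueError("read counts must be non-negative")
    l_chip_arr = np.atleast_1d(np.asarray(l_chip, dtype=np.float64))
    l_control_arr = np.atleast_1d(np.asarray(l_control, dtype=np.float64))
    if (l_chip_arr <= 0).any() or (l_control_arr <= 0).any():
        raise ValueError("region lengths must be positive")
    nc = _round_half_up(n_chip_arr / l_chip_arr * l_pval)
    nk = _round_half_up(n_control_arr / l_control_arr * l_pval)
    total = nc + nk
    k = nc - 1 if inclusive else nc
    with np.errstate(invalid="ignore"):
        p = binom.sf(k, total, 0.5)
    p = np.atleast_1d(np.asarray(p, dtype=np.float64))
    p[np.atleast_1d(total) == 0] = 1.0
    if np.isscalar(n_chip) and np.isscalar(n_control):
        return float(p[0])
    return p


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Sorted P-values are scaled by N/rank, made monotone non-increasing
    from the largest rank down, clipped at 1, and returned in the input
    order.
    """
    p = np.asarray(p_values, dtype=np.float64)
    m = p.size
    if m == 0:
        return np.zeros(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def _log_binom_tail_counts(
    n_chip: np.ndarray, n_control_scaled: np.ndarray
) -> np.ndarray:
    """log of the upper-tail binomial P-value on commensurate counts.

    Strong regions push the tail below the double-precision floor, which
    would flatten a minimization objective to all-zeros; when ``sf``
    underflows the tail is evaluated in log space from its leading term
    with a geometric-series bound on the remainder (tight in the far
    tail, where underflow happens).
    """
    nc = np.atleast_1d(np.asarray(n_chip, dtype=np.int64))
    nk = _round_half_up(n_control_scaled)
    total = nc + nk
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.atleast_1d(np.asarray(binom.sf(nc, total, 0.5), dtype=np.float64))
        logp = np.log(p)
    logp[total == 0] = 0.0  # empty region: p = 1
    underflow = (p == 0.0) & (nc < total) & (total > 0)
    if np.any(underflow):
        n = total[underflow].astype(np.float64)
        r = nc[underflow].astype(np.float64) + 1.0
        leading = (
            gammaln(n + 1.0) - gammaln(r + 1.0) - gammaln(n - r + 1.0)
            - n * np.log(2.0)
        )
        ratio = (n - r) / (r + 1.0)  # < 1 in the far tail
        logp[underflow] = leading - np.log1p(-ratio)
    logp[(nc >= total) & (total > 0)] = -np.inf  # zero control: exact 0
    return logp


def trim_pvalue_min(
    interval: GenomicInterval,
    chip_reads: FragmentIndex,
    control_reads: FragmentIndex,
    rho: float,
) -> GenomicInterval:
    """Refine region ends to the binomial-P-value minimizing sub-region.

    First the start is moved to the position minimizing the P-value of
    [start, end) with the test window equal to the sub-region's own
    length; then, keeping the new start, the end is minimized likewise.
    Ties are broken toward the wider region.  Because the test window
    tracks the sub-region length, the normalized counts are the raw counts
    (control scaled by rho).
    """
    i, j = interval.start, interval.end
    starts = np.arange(i, j, dtype=np.int64)
    n_chip = chip_reads.count_many(starts, np.full(starts.size, j))
    n_ctrl = control_reads.count_many(starts, np.full(starts.size, j))
    logp = _log_binom_tail_counts(n_chip, rho * n_ctrl)
    i2 = int(i + np.argmin(logp))  # first minimum -> smallest start
    ends = np.arange(i2 + 1, j + 1, dtype=np.int64)
    n_chip = chip_reads.count_many(np.full(ends.size, i2), ends)
    n_ctrl = control_reads.count_many(np.full(ends.size, i2), ends)
    logp = _log_binom_tail_counts(n_chip, rho * n_ctrl)
    j2 = int(i2 + 1 + (logp.size - 1 - np.argmin(logp[::-1])))  # last min -> largest end
    return GenomicInterval(interval.chrom, i2, j2)


def strand_concordance_filter(
    interval: GenomicInterval,
    plus_profile: SignalProfile,
    minus_profile: SignalProfile,
) -> bool:
    """True (keep) when the strand signal totals agree within a factor of 2.

    The region is discarded when ``min(S+/S-, S-/S+) < 0.5``; a region
    with signal on only one strand, or on neither, is discarded.
    """
    s_plus = float(plus_profile.values[interval.start : interval.end].sum())
    s_minus = float(minus_profile.values[interval.start : interval.end].sum())
    if s_plus == 0.0 or s_minus == 0.0:
        return False
    return min(s_plus / s_minus, s_minus / s_plus) >= 0.5


def find_summit(er: GenomicInterval, raw: SignalProfile) -> int:
    """Leftmost position of maximal corrected signal inside the region."""
    window = raw.values[er.start : er.end]
    return int(er.start + np.argmax(window))


def find_trough(
    er: GenomicInterval,
    raw: SignalProfile,
    mm: MultiMappabilityProfile,
    window: int = DEFAULT_TROUGH_WINDOW,
) -> int | None:
    """Signal minimum between the two tallest peaks, mappability permitting.

    The two tallest interior local maxima of the corrected signal inside
    the region are located; among the positions strictly between them,
    candidates are scanned in order of increasing signal and the first one
    whose surrounding *window* has mean multi-mappability below the exonic
    threshold is returned.  Regions with fewer than two local maxima, or
    no mappable valley position, yield None.
    """
    segment = raw.values[er.start : er.end]
    _, maxima = find_extrema(segment)
    if maxima.size < 2:
        return None
    heights = segment[maxima]
    top_two = maxima[np.argsort(-heights, kind="stable")[:2]]
    left, right = int(top_two.min()), int(top_two.max())
    if right - left < 2:
        return None
    between = np.arange(left + 1, right)
    order = np.argsort(segment[between], kind="stable")
    mm_values = mm.values
    n = mm_values.size
    half = window // 2
    for idx in order:
        pos = int(er.start + between[idx])
        lo, hi = max(0, pos - half), min(n, pos + half + 1)
        if mm_values[lo:hi].mean() < mm.m_exonic_threshold:
            return pos
    return None


def call_ers(
    ssers,
    corrected: dict[str, SignalProfile],
    rd_chip: dict[str, RDProfiles],
    chip_reads: dict[str, FragmentIndex],
    control_reads: dict[str, FragmentIndex],
    rho: float,
    l_pval: int,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    mm: dict[str, MultiMappabilityProfile] | None = None,
    trough_window: int = DEFAULT_TROUGH_WINDOW,
) -> list[EnrichedRegion]:
    """Merge SSERs across scales and call the final FDR-controlled ER set.

    Pipeline: interval union -> P-value-minimizing end refinement ->
    strand concordance filter -> binomial P-values at the configured
    ``l_pval`` -> BH q-values (genome-wide) -> keep q <= cutoff.  Each
    surviving region is annotated with its summit, trough (when a
    multi-mappability profile is supplied), and maximum SSER pileup scale.
    """
    if not 0 < q_cutoff <= 1:
        raise ValueError("q_cutoff must be in (0, 1]")
    ssers = list(ssers)
    merged = merge_ssers(ssers)
    candidates: list[GenomicInterval] = []
    for iv in merged:
        refined = trim_pvalue_min(iv, chip_reads[iv.chrom], control_reads[iv.chrom], rho)
        profiles = rd_chip[iv.chrom]
        if strand_concordance_filter(refined, profiles.plus, profiles.minus):
            candidates.append(refined)
    logger.info(
        "merged %d SSERs into %d regions, %d pass the strand filter",
        len(ssers), len(merged), len(candidates),
    )
    if not candidates:
        return []
    p_values = np.empty(len(candidates))
    chip_counts = np.empty(len(candidates), dtype=np.int64)
    ctrl_scaled = np.empty(len(candidates))
    for idx, iv in enumerate(candidates):
        n_chip = chip_reads[iv.chrom].count(iv.start, iv.end)
        n_ctrl = control_reads[iv.chrom].count(iv.start, iv.end)
        length = len(iv)
        # cap the test window at the region length: normalization may only
        # scale counts down (upscaling short regions breaks FDR control)
        p_values[idx] = binomial_pvalue(
            n_chip, rho * n_ctrl, length, length, min(l_pval, length)
        )
        chip_counts[idx] = n_chip
        ctrl_scaled[idx] = rho * n_ctrl
    q_values = bh_qvalues(p_values)

    pileup = _pileup_by_chrom(ssers, corrected)
    regions: list[EnrichedRegion] = []
    for idx, iv in enumerate(candidates):
        if q_values[idx] > q_cutoff:
            continue
        raw = corrected[iv.chrom]
        summit = find_summit(iv, raw)
        trough = None
        if mm is not None and iv.chrom in mm:
            trough = find_trough(iv, raw, mm[iv.chrom], trough_window)
        regions.append(
            EnrichedRegion(
                interval=iv,
                p_value=float(p_values[idx]),
                q_value=float(q_values[idx]),
                chip_count=int(chip_counts[idx]),
                control_count_normalized=float(ctrl_scaled[idx]),
                summit=summit,
                trough=trough,
                max_pileup_scale=int(pileup[iv.chrom][summit]),
            )
        )
    chrom_order = {c: k for k, c in enumerate(corrected)}
    regions.sort(key=lambda r: (chrom_order[r.interval.chrom], r.interval.start))
    logger.info("%d of %d candidate regions pass q <= %g", len(regions), len(candidates), q_cutoff)
    return regions


def _pileup_by_chrom(ssers, corrected: dict[str, SignalProfile]) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for c, p in corrected.items():
        length = len(p)
        delta = np.zeros(length + 1, dtype=np.int64)
        for s in ssers:
            if s.interval.chrom == c:
                delta[s.interval.start] += 1
                delta[s.interval.end] -= 1
        out[c] = np.cumsum(delta)[:length]
    return out
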