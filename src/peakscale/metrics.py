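"""Accuracy measures for benchmarking region calls against a gold standard.

All coverage arithmetic is in base pairs on merged interval sets:
sensitivity is the covered fraction of the gold set, positive predictive
value the correctly-covered fraction of the predictions, and the
F-measure their harmonic mean.  Reproducibility between replicates is the
symmetric mean overlap fraction.  Ranked-call measures (promoter recovery
curves, motif proximity of summits) evaluate score-ordered call lists.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .signal_io import GenomicInterval

__all__ = [
    "AccuracyReport",
    "coverage_accuracy",
    "overlap_fraction",
    "promoter_recovery_curve",
    "motif_proximity",
    "merge_intervals",
]


@dataclass(frozen=True)
class AccuracyReport:
    sensitivity: float
    ppv: float
    f_measure: float


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Coalesce overlapping or book-ended intervals into maximal ones."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def _coverage(intervals: Sequence[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


def _by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, list[list[int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, [[], []])
        out[iv.chrom][0].append(iv.start)
        out[iv.chrom][1].append(iv.end)
    return {c: (np.asarray(s), np.asarray(e)) for c, (s, e) in out.items()}


def _intersection_coverage(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Base pairs covered by both merged sets (two-pointer sweep)."""
    a_by = _by_chrom(a)
    b_by = _by_chrom(b)
    total = 0
    for chrom in set(a_by) & set(b_by):
        sa, ea = a_by[chrom]
        sb, eb = b_by[chrom]
        i = j = 0
        while i < sa.size and j < sb.size:
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += int(hi - lo)
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    return total


def coverage_accuracy(
    predicted: Sequence[GenomicInterval], gold: Sequence[GenomicInterval]
) -> AccuracyReport:
    """Base-pair sensitivity, PPV, and their harmonic mean (F-measure)."""
    if not gold:
        raise ValueError("gold-standard set is empty; sensitivity undefined")
    pred = merge_intervals(predicted)
    gold_m = merge_intervals(gold)
    inter = _intersection_coverage(pred, gold_m)
    covg_p = _coverage(pred)
    covg_g = _coverage(gold_m)
    sensitivity = inter / covg_g
    ppv = inter / covg_p if covg_p else 0.0
    if sensitivity + ppv == 0.0:
        f = 0.0
    else:
        f = 2 * sensitivity * ppv / (sensitivity + ppv)
    return AccuracyReport(sensitivity=sensitivity, ppv=ppv, f_measure=f)


def overlap_fraction(
    rep1: Sequence[GenomicInterval], rep2: Sequence[GenomicInterval]
) -> float:
    """Symmetric mean overlap fraction between two replicate call sets."""
    if not rep1 or not rep2:
        raise ValueError("overlap fraction needs two non-empty interval sets")
    a = merge_intervals(rep1)
    b = merge_intervals(rep2)
    inter = _intersection_coverage(a, b)
    return inter / (2 * _coverage(a)) + inter / (2 * _coverage(b))


def _overlap_with_merged(
    iv: GenomicInterval, merged: dict[str, tuple[np.ndarray, np.ndarray]]
) -> int:
    if iv.chrom not in merged:
        return 0
    starts, ends = merged[iv.chrom]
    lo = np.searchsorted(ends, iv.start, side="right")
    hi = np.searchsorted(starts, iv.end, side="left")
    if hi <= lo:
        return 0
    overlap = np.minimum(ends[lo:hi], iv.end) - np.maximum(starts[lo:hi], iv.start)
    return int(np.clip(overlap, 0, None).sum())


def promoter_recovery_curve(
    ers: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
    step: int = 1000,
    min_overlap_fraction: float = 0.05,
) -> list[tuple[int, float, float]]:
    """(prefix size, correct-call fraction, promoters-recovered fraction).

    *ers* must already be ranked best-first.  A call counts as correct
    when its overlap with the merged promoter set is at least
    *min_overlap_fraction* of the call's own length; a promoter is
    recovered once any correct call in the prefix overlaps it.
    """
    merged_prom = merge_intervals(promoters)
    prom_by = _by_chrom(merged_prom)
    n_prom = len(promoters)
    qualifies = [
        _overlap_with_merged(iv, prom_by) >= min_overlap_fraction * len(iv)
        for iv in ers
    ]
    curve: list[tuple[int, float, float]] = []
    sizes = list(range(step, len(ers) + 1, step))
    if not sizes or sizes[-1] != len(ers):
        sizes.append(len(ers))
    for size in sizes:
        prefix = list(ers[:size])
        correct = [iv for iv, ok in zip(prefix, qualifies[:size]) if ok]
        frac_correct = len(correct) / size if size else 0.0
        correct_by = _by_chrom(merge_intervals(correct)) if correct else {}
        recovered = sum(
            1 for prom in promoters if _overlap_with_merged(prom, correct_by) > 0
        )
        frac_recovered = recovered / n_prom if n_prom else 0.0
        curve.append((size, frac_correct, frac_recovered))
    return curve


def motif_proximity(
    summits: Sequence[tuple[str, int]],
    motifs: Sequence[tuple[str, int]],
    radius: int = 150,
    top_k: int = 2000,
) -> float:
    """Fraction of the top-k ranked summits within *radius* bp of a motif.

    The distance check is closed (<= radius); *summits* must be in rank
    order.
    """
    motif_by: dict[str, list[int]] = {}
    for chrom, pos in motifs:
        motif_by.setdefault(chrom, []).append(pos)
    motif_sorted = {c: np.sort(np.asarray(p)) for c, p in motif_by.items()}
    top = summits[:top_k]
    if not top:
        return 0.0
    hits = 0
    for chrom, pos in top:
        positions = motif_sorted.get(chrom)
        if positions is None or positions.size == 0:
            continue
        idx = np.searchsorted(positions, pos)
        best = min(
            abs(pos - positions[max(idx - 1, 0)]),
            abs(pos - positions[min(idx, positions.size - 1)]),
        )
        if best <= radius:
            hits += 1
    return hits / len(top)
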