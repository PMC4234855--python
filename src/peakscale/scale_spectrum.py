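"""SSER pileup scale: a per-base measure of enrichment broadness.

Pooling the SSERs from every smoothing scale and counting, at each
position, how many of them cover it gives the pileup scale: punctate
signals are covered by SSERs at only the smallest few scales while broad
domains accumulate cover across many scales.  The genome-wide histogram
of pileup values (the scale spectrum) characterizes a dataset's
enrichment length scales, and simple heuristics on it suggest the window
schedule and test-window parameters for an unfamiliar dataset.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .er_calls import merge_ssers
from .multiscale import ScaleSchedule
from .signal_io import GenomeTable

__all__ = [
    "PileupScaleProfile",
    "SpectrumHistogram",
    "ParameterSuggestion",
    "compute_pileup_scale",
    "spectrum_histogram",
    "suggest_parameters",
]

#: A scale must hold at least this fraction of all SSERs to anchor l_begin.
SIGNIFICANT_SSER_FRACTION = 0.01


@dataclass
class PileupScaleProfile:
    """Per-nucleotide count of SSERs (across scales) covering the position."""

    chrom: str
    values: np.ndarray


@dataclass
class SpectrumHistogram:
    """Positions per pileup-scale value, mapped to window lengths."""

    counts: np.ndarray  # index = pileup value, 0 .. n_scales
    schedule: ScaleSchedule

    def window_for_pileup(self, k: int) -> int:
        """Window length associated with pileup value k >= 1."""
        if k < 1:
            raise ValueError("pileup value must be >= 1")
        windows = self.schedule.windows
        return windows[min(k, len(windows)) - 1]

    @property
    def log_frequency(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log10(self.counts.astype(np.float64))


@dataclass(frozen=True)
class ParameterSuggestion:
    l_begin: int
    l_end: int
    l_pval: int
    l_spectrum: int
    mean_er_distance: float


def compute_pileup_scale(ssers, genome: GenomeTable) -> dict[str, PileupScaleProfile]:
    """Coverage count of pooled SSER intervals at every genome position."""
    out: dict[str, PileupScaleProfile] = {}
    deltas = {c: np.zeros(length + 1, dtype=np.int64) for c, length in genome}
    for s in ssers:
        iv = s.interval if hasattr(s, "interval") else s
        deltas[iv.chrom][iv.start] += 1
        deltas[iv.chrom][iv.end] -= 1
    for chrom, length in genome:
        out[chrom] = PileupScaleProfile(chrom, np.cumsum(deltas[chrom])[:length])
    return out


def spectrum_histogram(
    pileup: dict[str, PileupScaleProfile] | PileupScaleProfile,
    schedule: ScaleSchedule,
) -> SpectrumHistogram:
    """Histogram of pileup values over the genome; sums to genome length."""
    if isinstance(pileup, PileupScaleProfile):
        pileup = {pileup.chrom: pileup}
    n_scales = len(schedule)
    counts = np.zeros(n_scales + 1, dtype=np.int64)
    for prof in pileup.values():
        counts += np.bincount(prof.values, minlength=n_scales + 1)[: n_scales + 1]
    return SpectrumHistogram(counts=counts, schedule=schedule)


def suggest_parameters(
    spectrum: SpectrumHistogram,
    ssers,
    significant_fraction: float = SIGNIFICANT_SSER_FRACTION,
) -> ParameterSuggestion:
    """Heuristic window-schedule suggestions for an uncharacterized dataset.

    ``l_spectrum`` is the window length at the spectrum's global maximum
    (pileup 0, i.e. unenriched positions, excluded).  The end scale is
    ``min(2 x mean ER-to-ER gap, l_spectrum)``, with the gap measured
    between adjacent merged SSER regions; the begin scale is the smallest
    window whose scale holds at least *significant_fraction* of all
    SSERs; the test window is bounded by both.
    """
    ssers = list(ssers)
    if not ssers:
        raise ValueError("cannot characterize dataset: no SSERs")
    enriched = spectrum.counts[1:]
    if enriched.sum() == 0:
        raise ValueError("cannot characterize dataset: empty scale spectrum")
    l_spectrum = spectrum.window_for_pileup(int(np.argmax(enriched)) + 1)

    merged = merge_ssers(ssers)
    gaps: list[int] = []
    for prev, cur in zip(merged, merged[1:]):
        if prev.chrom == cur.chrom:
            gaps.append(cur.start - prev.end)
    mean_gap = float(np.mean(gaps)) if gaps else float("inf")
    l_end = int(min(2 * mean_gap, l_spectrum))

    windows = spectrum.schedule.windows
    per_scale = np.zeros(len(windows), dtype=np.int64)
    for s in ssers:
        per_scale[s.scale_index] += 1
    threshold = significant_fraction * len(ssers)
    significant = np.flatnonzero(per_scale >= threshold)
    l_begin = windows[int(significant[0])] if significant.size else windows[0]

    l_pval = min(l_spectrum, l_end)
    return ParameterSuggestion(
        l_begin=int(l_begin),
        l_end=int(l_end),
        l_pval=int(l_pval),
        l_spectrum=int(l_spectrum),
        mean_er_distance=mean_gap,
    )
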