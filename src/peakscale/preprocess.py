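"""Read preprocessing: deduplication, read-depth profiles, control
normalization, and the mappability correction filter.

The correction filter replaces each position of the ChIP profile by the
maximum of itself and the median signal at *mappable* positions within a
window around it.  Because the median is taken only over positions whose
multi-mappability is below the exonic threshold, dips carved into the
signal by repeat-induced read loss are filled back to the local mappable
background, while genuinely high positions are left untouched (the output
never drops below the input anywhere -- a dilation).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _filters
from .mappability import MultiMappabilityProfile, mappable_mask
from .signal_io import GenomeTable, Read, SignalProfile

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationFit",
    "RDProfiles",
    "FragmentIndex",
    "deduplicate",
    "build_rd_profile",
    "build_fragment_index",
    "estimate_normalization_factor",
    "correct_mappability",
]

DEFAULT_FRAGMENT_LENGTH = 200
DEFAULT_BIN_LENGTH = 10_000
DEFAULT_CORRECTION_WINDOW = 2_000


@dataclass(frozen=True)
class NormalizationFit:
    """Least-squares slope (through the origin) of binned ChIP vs control totals."""

    rho: float
    bin_length: int
    n_bins: int


@dataclass
class RDProfiles:
    """Per-strand and combined read-depth profiles for one chromosome."""

    plus: SignalProfile
    minus: SignalProfile
    total: SignalProfile


class FragmentIndex:
    """Sorted fragment endpoints for O(log n) interval overlap counting."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray):
        self.starts = np.sort(np.asarray(starts, dtype=np.int64))
        self.ends = np.sort(np.asarray(ends, dtype=np.int64))
        if self.starts.size != self.ends.size:
            raise ValueError("starts and ends must have equal length")
        self.n = int(self.starts.size)

    def count(self, start: int, end: int) -> int:
        return int(self.count_many(np.asarray([start]), np.asarray([end]))[0])

    def count_many(self, starts, ends) -> np.ndarray:
        """Number of fragments overlapping each [start, end)."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        ending_before = np.searchsorted(self.ends, starts, side="right")
        starting_after = self.n - np.searchsorted(self.starts, ends, side="left")
        return self.n - ending_before - starting_after


def deduplicate(reads: list[Read], max_per_position: int = 1) -> list[Read]:
    """Keep at most *max_per_position* reads per (chrom, 5' position, strand).

    Retention is order-stable: the first occurrences win.
    """
    if max_per_position < 1:
        raise ValueError("max_per_position must be >= 1")
    seen: dict[tuple[str, int, str], int] = {}
    kept: list[Read] = []
    for read in reads:
        key = (read.chrom, read.pos5, read.strand)
        count = seen.get(key, 0)
        if count < max_per_position:
            kept.append(read)
            seen[key] = count + 1
    return kept


def _fragment_bounds(
    reads: list[Read], chrom_length: int, fragment_length: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extend reads to fragments from the 5' end, clipped at chromosome bounds."""
    n = len(reads)
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    is_plus = np.empty(n, dtype=bool)
    for i, read in enumerate(reads):
        if read.strand == "+":
            s = read.pos5
            e = read.pos5 + fragment_length
            is_plus[i] = True
        else:
            e = read.pos5 + 1
            s = e - fragment_length
            is_plus[i] = False
        starts[i] = max(s, 0)
        ends[i] = min(e, chrom_length)
    valid = starts < ends
    return starts[valid], ends[valid], is_plus[valid]


def _pileup(starts: np.ndarray, ends: np.ndarray, length: int) -> np.ndarray:
    delta = np.zeros(length + 1, dtype=np.int64)
    np.add.at(delta, starts, 1)
    np.add.at(delta, ends, -1)
    return np.cumsum(delta)[:length]


def build_rd_profile(
    reads: dict[str, list[Read]],
    genome: GenomeTable,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
) -> dict[str, RDProfiles]:
    """Per-nucleotide fragment coverage, with separate +/- strand profiles.

    Each read is extended to *fragment_length* from its 5' end in the
    strand direction and clipped at the chromosome bounds; profile values
    count the extended fragments covering each nucleotide.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    out: dict[str, RDProfiles] = {}
    for chrom, length in genome:
        chrom_reads = reads.get(chrom, [])
        starts, ends, is_plus = _fragment_bounds(chrom_reads, length, fragment_length)
        plus = _pileup(starts[is_plus], ends[is_plus], length)
        minus = _pileup(starts[~is_plus], ends[~is_plus], length)
        out[chrom] = RDProfiles(
            plus=SignalProfile(chrom, plus),
            minus=SignalProfile(chrom, minus),
            total=SignalProfile(chrom, plus + minus),
        )
    return out


def build_fragment_index(
    reads: dict[str, list[Read]],
    genome: GenomeTable,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
) -> dict[str, FragmentIndex]:
    out: dict[str, FragmentIndex] = {}
    for chrom, length in genome:
        starts, ends, _ = _fragment_bounds(reads.get(chrom, []), length, fragment_length)
        out[chrom] = FragmentIndex(starts, ends)
    return out


def _bin_totals(values: np.ndarray, bin_length: int) -> np.ndarray:
    edges = np.arange(0, values.size, bin_length)
    return np.add.reduceat(values.astype(np.float64), edges)


def estimate_normalization_factor(
    chip: dict[str, SignalProfile] | SignalProfile,
    control: dict[str, SignalProfile] | SignalProfile,
    bin_length: int = DEFAULT_BIN_LENGTH,
) -> NormalizationFit:
    """Slope of the zero-intercept least-squares fit of binned ChIP on control.

    Chromosomes are cut into *bin_length* bins, total signal per bin is
    computed for both samples, and the slope minimizing
    ``sum_i (w_i - rho * c_i)^2`` is returned in closed form:
    ``rho = sum(w c) / sum(c^2)``.  Bins are pooled over all chromosomes.
    """
    if isinstance(chip, SignalProfile):
        chip = {chip.chrom: chip}
    if isinstance(control, SignalProfile):
        control = {control.chrom: control}
    if set(chip) != set(control):
        raise ValueError("ChIP and control profiles cover different chromosomes")
    if bin_length < 1:
        raise ValueError("bin_length must be >= 1")
    w_parts, c_parts = [], []
    for chrom in chip:
        if len(chip[chrom]) != len(control[chrom]):
            raise ValueError(f"profile length mismatch on {chrom!r}")
        if len(chip[chrom]) == 0:
            continue
        w_parts.append(_bin_totals(chip[chrom].values, bin_length))
        c_parts.append(_bin_totals(control[chrom].values, bin_length))
    w = np.concatenate(w_parts) if w_parts else np.zeros(0)
    c = np.concatenate(c_parts) if c_parts else np.zeros(0)
    denom = float(np.dot(c, c))
    if denom == 0.0:
        raise ValueError("cannot normalize: control signal is identically zero")
    rho = float(np.dot(w, c)) / denom
    return NormalizationFit(rho=rho, bin_length=bin_length, n_bins=int(w.size))


def correct_mappability(
    chip: SignalProfile,
    mm: MultiMappabilityProfile,
    l_c: int = DEFAULT_CORRECTION_WINDOW,
) -> SignalProfile:
    """Fill repeat-induced signal dips with the local mappable median.

    For every position i the median of the signal at mappable positions
    within ``[i - l_c/2, i + l_c/2]`` is computed and the output is the
    maximum of the input value and that median; windows containing no
    mappable position pass the input through.  The input is floored to
    integers first so that downstream histogram medians stay exact.
    """
    if l_c <= 0 or l_c % 2 != 0:
        raise ValueError("l_c must be a positive even window length")
    if len(chip) != len(mm):
        raise ValueError("signal and multi-mappability profiles differ in length")
    x = np.floor(chip.values).astype(np.int64)
    mask = mappable_mask(mm)
    corrected = _filters.masked_dilation(x, mask, l_c // 2)
    return SignalProfile(chip.chrom, corrected)
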