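"""Per-nucleotide multi-mappability profiles.

The multi-mappability value of a position is the average multiplicity with
which read-length fragments overlapping it map to the genome: exactly 1 in
uniquely mappable sequence, larger inside repeats.  The profile drives the
mappability correction filter (positions with a value at or above the
exonic threshold, 1.2 by default, are excluded from the correction median)
and the trough-reporting guard.

Profiles are built here by exact k-mer multiplicity counting on both
strands, which is deterministic and exact for the desk-scale genomes this
package generates; precomputed profiles for real genomes can be loaded
from bedGraph.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .signal_io import GenomeTable, read_bedgraph

logger = logging.getLogger(__name__)

__all__ = [
    "MultiMappabilityProfile",
    "build_multimappability",
    "load_multimappability",
    "is_mappable",
    "mappable_mask",
    "DEFAULT_EXONIC_THRESHOLD",
]

#: Default mappability cutoff: the smallest multi-mappability observed over
#: exons and promoters in well-mapped genomes.  Positions with a value at or
#: above it are treated as unreliable for the correction median.
DEFAULT_EXONIC_THRESHOLD = 1.2

_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgtNn", b"TGCATGCANN"):
    _COMPLEMENT[_a] = _b


@dataclass
class MultiMappabilityProfile:
    """Per-nucleotide average mapping multiplicity for one chromosome.

    Values are >= 1 wherever at least one fragment covers the position;
    uncovered positions (chromosome ends shorter than a fragment) are 0 and
    treated as non-mappable.
    """

    chrom: str
    values: np.ndarray
    m_exonic_threshold: float = DEFAULT_EXONIC_THRESHOLD

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.m_exonic_threshold <= 1:
            raise ValueError("m_exonic_threshold must be > 1")

    def __len__(self) -> int:
        return int(self.values.size)


def _load_sequences(source) -> dict[str, bytes]:
    if isinstance(source, dict):
        return {name: seq.upper().encode() if isinstance(seq, str) else bytes(seq).upper()
                for name, seq in source.items()}
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper().encode()
            for rec in SeqIO.parse(str(source), "fasta")}


def build_multimappability(
    genome_sequence: str | Path | dict[str, str],
    read_length: int,
    max_hits: int = 5,
    m_exonic_threshold: float = DEFAULT_EXONIC_THRESHOLD,
) -> dict[str, MultiMappabilityProfile]:
    """Exact multi-mappability from k-mer multiplicity counting.

    Every read-length fragment of the genome is looked up against all
    fragments of both strands; its occurrence count, capped at *max_hits*,
    is laid down as read depth over the fragment footprint.  The final
    value at a position is that accumulated depth divided by the number of
    fragments overlapping the position, so uniquely mappable sequence gets
    exactly 1.

    *genome_sequence* may be a FASTA path or a ``{name: sequence}`` dict.
    """
    if read_length < 10:
        raise ValueError("read_length must be >= 10")
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    seqs = _load_sequences(genome_sequence)
    k = int(read_length)
    for name, s in seqs.items():
        if k > len(s):
            raise ValueError(
                f"read_length {k} exceeds chromosome {name!r} length {len(s)}"
            )

    # Occurrence counting: a fragment's hits across both strands equal its
    # count among all forward k-mers plus its count among the k-mers of the
    # reverse-complemented genome.
    fwd_blocks: list[np.ndarray] = []
    rc_blocks: list[np.ndarray] = []
    slices: dict[str, tuple[int, int]] = {}
    offset = 0
    for name, s in seqs.items():
        arr = np.frombuffer(s, dtype=np.uint8)
        fwd = sliding_window_view(arr, k)
        rc = sliding_window_view(_COMPLEMENT[arr][::-1], k)
        fwd_blocks.append(fwd)
        rc_blocks.append(rc)
        slices[name] = (offset, offset + fwd.shape[0])
        offset += fwd.shape[0]
    n_fwd = offset
    combined = np.ascontiguousarray(np.concatenate(fwd_blocks + rc_blocks, axis=0))
    as_void = combined.view(np.dtype((np.void, k))).ravel()
    _, inverse, counts = np.unique(as_void, return_inverse=True, return_counts=True)
    occ_fwd = counts[inverse[:n_fwd]]

    out: dict[str, MultiMappabilityProfile] = {}
    for name, s in seqs.items():
        length = len(s)
        lo, hi = slices[name]
        occ = np.minimum(occ_fwd[lo:hi], max_hits).astype(np.float64)
        n_frag = hi - lo
        depth_delta = np.zeros(length + 1, dtype=np.float64)
        depth_delta[:n_frag] += occ
        depth_delta[k : k + n_frag] -= occ
        depth = np.cumsum(depth_delta)[:length]
        cov_delta = np.zeros(length + 1, dtype=np.float64)
        cov_delta[:n_frag] += 1.0
        cov_delta[k : k + n_frag] -= 1.0
        cov = np.cumsum(cov_delta)[:length]
        values = np.zeros(length, dtype=np.float64)
        covered = cov > 0
        values[covered] = depth[covered] / cov[covered]
        out[name] = MultiMappabilityProfile(name, values, m_exonic_threshold)
    return out


def load_multimappability(
    path: str | Path,
    genome: GenomeTable,
    threshold: float = DEFAULT_EXONIC_THRESHOLD,
) -> dict[str, MultiMappabilityProfile]:
    """Load a precomputed multi-mappability bedGraph.

    Positions absent from the file get 0 (non-mappable); overlapping
    records or records beyond a chromosome end raise.
    """
    dense = read_bedgraph(path, genome)
    out: dict[str, MultiMappabilityProfile] = {}
    for chrom, values in dense.items():
        if values.size and values.min() < 0:
            raise ValueError(f"negative multi-mappability values on {chrom!r}")
        out[chrom] = MultiMappabilityProfile(chrom, values, threshold)
    return out


def mappable_mask(profile: MultiMappabilityProfile) -> np.ndarray:
    """Boolean mask of positions usable by the correction median."""
    v = profile.values
    return (v > 0) & (v < profile.m_exonic_threshold)


def is_mappable(profile: MultiMappabilityProfile, pos: int) -> bool:
    """True iff the position has evidence of unique mappability.

    A position qualifies when its multi-mappability is strictly between 0
    (covered by at least one fragment) and the exonic threshold.
    """
    if pos < 0 or pos >= profile.values.size:
        raise IndexError(f"position {pos} outside chromosome {profile.chrom!r}")
    v = profile.values[pos]
    return bool(0 < v < profile.m_exonic_threshold)
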