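"""Genomic primitives and plain-text I/O.

Everything downstream is built on four small containers: a :class:`Read`
(one aligned read reduced to its 5' anchor), a :class:`SignalProfile`
(dense per-nucleotide read-depth vector for one chromosome), a
:class:`GenomicInterval`, and a :class:`GenomeTable` (ordered chromosome
name/length list).

Coordinates are 0-based, half-open everywhere: in memory, in BED, and in
bedGraph.  All files are tab-separated plain text.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Read",
    "SignalProfile",
    "GenomicInterval",
    "GenomeTable",
    "load_reads",
    "read_bed_intervals",
    "write_bed",
    "write_bedgraph",
    "read_bedgraph",
]


@dataclass(frozen=True)
class Read:
    """A single aligned, duplicate-filterable read.

    Only the 5' end position matters for fragment extension; the read is
    later extended to the library fragment length in its strand direction.
    """

    chrom: str
    pos5: int
    strand: str
    read_length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pos5 < 0:
            raise ValueError(f"pos5 must be non-negative, got {self.pos5}")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


@dataclass
class SignalProfile:
    """Dense non-negative per-nucleotide signal for one chromosome."""

    chrom: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("signal profile must be one-dimensional")
        if self.values.size and self.values.min() < 0:
            raise ValueError("signal profile values must be non-negative")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


class GenomeTable:
    """Ordered list of (chromosome name, length) pairs."""

    def __init__(self, entries: Iterable[tuple[str, int]]):
        self._names: list[str] = []
        self._lengths: dict[str, int] = {}
        for name, length in entries:
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            self._names.append(name)
            self._lengths[name] = length

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeTable":
        entries = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'name length'")
                try:
                    entries.append((fields[0], int(fields[1])))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad length field") from exc
        return cls(entries)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in self._names:
                fh.write(f"{name}\t{self._lengths[name]}\n")

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def length_of(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[tuple[str, int]]:
        for name in self._names:
            yield name, self._lengths[name]

    def __len__(self) -> int:
        return len(self._names)

    def total_length(self) -> int:
        return sum(self._lengths.values())


def load_reads(path: str | Path, genome: GenomeTable) -> dict[str, list[Read]]:
    """Load 6-column BED / tagAlign reads, keyed by chromosome.

    The 5' end is ``start`` for + reads and ``end - 1`` for - reads.
    Reads on chromosomes absent from *genome* are skipped with a warning;
    malformed lines raise with their line number.
    """
    by_chrom: dict[str, list[Read]] = {}
    skipped: dict[str, int] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            strand = fields[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: bad interval [{start}, {end})")
            n_lines += 1
            if chrom not in genome:
                skipped[chrom] = skipped.get(chrom, 0) + 1
                continue
            pos5 = start if strand == "+" else end - 1
            by_chrom.setdefault(chrom, []).append(
                Read(chrom=chrom, pos5=pos5, strand=strand, read_length=end - start)
            )
    if skipped:
        logger.warning(
            "skipped %d reads on chromosomes not in the genome table: %s",
            sum(skipped.values()),
            ", ".join(sorted(skipped)),
        )
    if n_lines == 0:
        logger.warning("no reads found in %s", path)
    return by_chrom


def read_bed_intervals(path: str | Path) -> list[tuple[GenomicInterval, float | None]]:
    """Read BED intervals, returning (interval, score-or-None) pairs."""
    out: list[tuple[GenomicInterval, float | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            score: float | None = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            out.append((iv, score))
    return out


def _region_fields(region) -> tuple[GenomicInterval, float | None]:
    if isinstance(region, GenomicInterval):
        return region, None
    iv = getattr(region, "interval", None)
    if iv is None:
        raise TypeError(f"cannot write {type(region).__name__} as a BED region")
    return iv, getattr(region, "q_value", None)


def write_bed(regions: Sequence, path: str | Path) -> None:
    """Write regions as BED6 with the q-value (when present) in the score field.

    Regions must already be sorted by (chromosome, start); a chromosome may
    not reappear after another chromosome has started.
    """
    seen_chroms: list[str] = []
    prev_start = -1
    with open(path, "w") as fh:
        for region in regions:
            iv, q = _region_fields(region)
            if not seen_chroms or iv.chrom != seen_chroms[-1]:
                if iv.chrom in seen_chroms:
                    raise ValueError("regions are not sorted by chromosome")
                seen_chroms.append(iv.chrom)
                prev_start = -1
            if iv.start < prev_start:
                raise ValueError("regions are not sorted by start coordinate")
            prev_start = iv.start
            score = "." if q is None else format(q, ".6g")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{score}\t.\n")


def _profile_items(profiles) -> list[tuple[str, np.ndarray]]:
    if isinstance(profiles, SignalProfile):
        return [(profiles.chrom, profiles.values)]
    if isinstance(profiles, dict):
        return [(c, p.values if isinstance(p, SignalProfile) else np.asarray(p))
                for c, p in profiles.items()]
    raise TypeError("expected a SignalProfile or a dict of them")


def write_bedgraph(profiles, path: str | Path) -> None:
    """Write profile(s) as run-length-compressed bedGraph.

    Consecutive equal values are merged into a single record (including
    zero runs), so reading the file back reproduces the profile exactly.
    Values are printed with up to 6 significant digits; adjacent runs whose
    formatted values coincide are merged as well.
    """
    with open(path, "w") as fh:
        for chrom, values in _profile_items(profiles):
            v = np.asarray(values)
            if v.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [v.size]))
            prev_text = None
            run_start = 0
            for s, e in zip(starts, ends):
                text = format(float(v[s]), ".6g")
                if prev_text is None:
                    prev_text, run_start = text, int(s)
                elif text != prev_text:
                    fh.write(f"{chrom}\t{run_start}\t{int(s)}\t{prev_text}\n")
                    prev_text, run_start = text, int(s)
            fh.write(f"{chrom}\t{run_start}\t{int(ends[-1])}\t{prev_text}\n")


def read_bedgraph(
    path: str | Path,
    genome: GenomeTable,
    *,
    allow_overlap: bool = False,
) -> dict[str, np.ndarray]:
    """Read a bedGraph into dense per-nucleotide vectors.

    Positions absent from the file are 0.  Records beyond a chromosome end
    or (by default) overlapping records raise; unknown chromosomes raise.
    """
    records: dict[str, list[tuple[int, int, float]]] = {c: [] for c, _ in genome}
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: bad interval [{start}, {end})")
            if end > genome.length_of(chrom):
                raise ValueError(
                    f"{path}:{lineno}: interval end {end} beyond chromosome "
                    f"{chrom!r} length {genome.length_of(chrom)}"
                )
            records[chrom].append((start, end, value))
            n_records += 1
    if n_records == 0:
        logger.warning("empty bedGraph %s; all-zero profiles returned", path)
    out: dict[str, np.ndarray] = {}
    for chrom, length in genome:
        v = np.zeros(length, dtype=np.float64)
        recs = sorted(records[chrom])
        prev_end = -1
        for start, end, value in recs:
            if not allow_overlap and start < prev_end:
                raise ValueError(f"overlapping bedGraph records on {chrom!r}")
            prev_end = max(prev_end, end)
            v[start:end] = value
        out[chrom] = v
    return out
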