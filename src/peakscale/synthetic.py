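"""Self-contained synthetic ChIP-seq fixtures.

Generates a random genome carrying exact duplicated repeat blocks (the
ground-truth low-mappability zones), and ChIP/control read sets with
enriched regions planted at known locations, folds, and length scales.
Fragments are sampled as a per-base Poisson process on fragment
midpoints: a flat background rate everywhere, multiplied by the fold
inside a planted region (rectangular) or by a triangular profile rising
to the fold at the region centre (peaked).  Each fragment yields one
read anchored at the fragment's 5' or 3' end with equal probability,
reproducing the strand-flanking geometry of real ChIP fragments.

Multi-mapping signal loss is emulated by re-assigning every read whose 5'
end falls inside a repeat copy to the same offset in a uniformly chosen
copy of that repeat family -- the mechanism the mappability correction
filter exists to repair.  With a fixed seed the entire fixture is
bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_io import GenomeTable, GenomicInterval, Read

__all__ = [
    "PlantedER",
    "RepeatFamily",
    "FixtureSpec",
    "Fixture",
    "default_fixture_spec",
    "null_fixture_spec",
    "make_genome",
    "simulate_reads",
    "write_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedER:
    start: int
    end: int
    fold: float
    shape: str = "rectangular"  # or "peaked"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("planted region start must be < end")
        if self.fold <= 1:
            raise ValueError("planted fold must be > 1")
        if self.shape not in ("rectangular", "peaked"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class RepeatFamily:
    """A source block and the positions of its exact copies."""

    source: tuple[int, int]
    copy_starts: tuple[int, ...]

    @property
    def length(self) -> int:
        return self.source[1] - self.source[0]

    def intervals(self) -> list[tuple[int, int]]:
        ivs = [self.source]
        ivs += [(s, s + self.length) for s in self.copy_starts]
        return ivs


@dataclass
class FixtureSpec:
    """The study conditions the generator emulates."""

    genome_length: int = 5_000_000
    chrom: str = "synth1"
    repeat_blocks: tuple[RepeatFamily, ...] = ()
    background_rate: float = 0.05  # fragments per bp
    planted_ers: tuple[PlantedER, ...] = ()
    fragment_length: int = 200
    read_length: int = 36
    control_depth_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        ers = sorted(self.planted_ers, key=lambda e: e.start)
        for prev, cur in zip(ers, ers[1:]):
            if cur.start < prev.end:
                raise ValueError("planted regions must be pairwise disjoint")
        for fam in self.repeat_blocks:
            for s, e in fam.intervals():
                if s < 0 or e > self.genome_length:
                    raise ValueError("repeat block outside the genome")


def default_fixture_spec(seed: int = 0) -> FixtureSpec:
    """The default study conditions: a 5 Mbp chromosome with ten regions
    planted at 8-fold enrichment across the 200 bp - 20 kbp length range,
    0.05 background fragments per bp, and two repeat families.

    One repeat source sits inside the 16 kbp planted region, so the ChIP
    profile carries a genuine repeat-induced dip for the correction
    filter to repair; the second family occupies plain background.
    """
    lengths = [200, 200, 500, 1000, 2000, 5000, 8000, 12000, 16000, 20000]
    anchors = [
        200_000, 400_000, 600_000, 900_000, 1_300_000,
        1_700_000, 2_200_000, 2_800_000, 3_400_000, 4_200_000,
    ]
    shapes = ["peaked", "peaked", "peaked", "rectangular", "rectangular",
              "rectangular", "rectangular", "rectangular", "rectangular",
              "rectangular"]
    ers = tuple(
        PlantedER(start=a, end=a + l, fold=8.0, shape=sh)
        for a, l, sh in zip(anchors, lengths, shapes)
    )
    repeats = (
        # source inside the 16 kbp region (3,400,000-3,416,000)
        RepeatFamily(source=(3_406_000, 3_408_000), copy_starts=(4_600_000, 4_800_000)),
        # background-only family
        RepeatFamily(source=(100_000, 101_000), copy_starts=(150_000,)),
    )
    return FixtureSpec(planted_ers=ers, repeat_blocks=repeats, seed=seed)


def null_fixture_spec(seed: int = 0) -> FixtureSpec:
    """Default conditions with nothing planted: ChIP and control exchangeable."""
    spec = default_fixture_spec(seed)
    return FixtureSpec(
        genome_length=spec.genome_length,
        chrom=spec.chrom,
        repeat_blocks=spec.repeat_blocks,
        background_rate=spec.background_rate,
        planted_ers=(),
        fragment_length=spec.fragment_length,
        read_length=spec.read_length,
        control_depth_ratio=spec.control_depth_ratio,
        seed=seed,
    )


@dataclass
class Fixture:
    spec: FixtureSpec
    sequences: dict[str, str]
    genome: GenomeTable
    truth: list[GenomicInterval]


def make_genome(spec: FixtureSpec) -> Fixture:
    """Random genome with exact duplicated repeat blocks at recorded positions."""
    rng = np.random.default_rng(spec.seed)
    seq = _BASES[rng.integers(0, 4, size=spec.genome_length)]
    for fam in spec.repeat_blocks:
        s0, e0 = fam.source
        block = seq[s0:e0].copy()
        for start in fam.copy_starts:
            seq[start : start + fam.length] = block
    sequences = {spec.chrom: seq.tobytes().decode()}
    genome = GenomeTable([(spec.chrom, spec.genome_length)])
    truth = [GenomicInterval(spec.chrom, er.start, er.end) for er in spec.planted_ers]
    return Fixture(spec=spec, sequences=sequences, genome=genome, truth=truth)


def _rate_vector(spec: FixtureSpec, rate: float, with_ers: bool) -> np.ndarray:
    lam = np.full(spec.genome_length, rate, dtype=np.float64)
    if with_ers:
        for er in spec.planted_ers:
            if er.shape == "rectangular":
                lam[er.start : er.end] *= er.fold
            else:
                half = (er.end - er.start) / 2.0
                offsets = np.arange(er.start, er.end) - er.start
                tri = 1.0 - np.abs(offsets - half) / half
                lam[er.start : er.end] *= 1.0 + (er.fold - 1.0) * tri
    return lam


def _sample_reads(
    spec: FixtureSpec, lam: np.ndarray, rng: np.random.Generator
) -> list[Read]:
    counts = rng.poisson(lam)
    midpoints = np.repeat(np.arange(spec.genome_length, dtype=np.int64), counts)
    half = spec.fragment_length // 2
    frag_starts = np.clip(midpoints - half, 0, spec.genome_length - 1)
    frag_ends = np.clip(midpoints - half + spec.fragment_length, 1, spec.genome_length)
    plus = rng.integers(0, 2, size=midpoints.size).astype(bool)
    pos5 = np.where(plus, frag_starts, frag_ends - 1)

    # Multi-mapping loss: reads inside a repeat copy keep their offset but
    # land in a uniformly chosen copy of the family.
    for fam in spec.repeat_blocks:
        intervals = fam.intervals()
        starts = np.asarray([iv[0] for iv in intervals], dtype=np.int64)
        masks = [(pos5 >= s) & (pos5 < s + fam.length) for s, _ in intervals]
        for (s, _), mask in zip(intervals, masks):
            n = int(mask.sum())
            if n == 0:
                continue
            chosen = starts[rng.integers(0, starts.size, size=n)]
            pos5[mask] = chosen + (pos5[mask] - s)

    reads = [
        Read(
            chrom=spec.chrom,
            pos5=int(p),
            strand="+" if is_plus else "-",
            read_length=spec.read_length,
        )
        for p, is_plus in zip(pos5, plus)
    ]
    return reads


def simulate_reads(
    spec: FixtureSpec, rng: np.random.Generator | None = None
) -> tuple[dict[str, list[Read]], dict[str, list[Read]]]:
    """ChIP and matched control read sets for the fixture conditions."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    chip_lam = _rate_vector(spec, spec.background_rate, with_ers=True)
    ctrl_lam = _rate_vector(
        spec, spec.background_rate * spec.control_depth_ratio, with_ers=False
    )
    chip = {spec.chrom: _sample_reads(spec, chip_lam, rng)}
    control = {spec.chrom: _sample_reads(spec, ctrl_lam, rng)}
    return chip, control


def write_reads_bed(reads: dict[str, list[Read]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in reads:
            for i, r in enumerate(reads[chrom]):
                if r.strand == "+":
                    start, end = r.pos5, r.pos5 + r.read_length
                else:
                    start, end = r.pos5 + 1 - r.read_length, r.pos5 + 1
                start = max(start, 0)
                fh.write(f"{chrom}\t{start}\t{end}\tr{i}\t0\t{r.strand}\n")


def write_fixture(fixture: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, genome table, reads, and truth BED to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_fasta": out / "genome.fa",
        "genome_table": out / "genome.txt",
        "chip_bed": out / "chip.bed",
        "control_bed": out / "control.bed",
        "truth_bed": out / "truth.bed",
    }
    with open(paths["genome_fasta"], "w") as fh:
        for chrom, seq in fixture.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    fixture.genome.to_file(paths["genome_table"])
    chip, control = simulate_reads(fixture.spec)
    write_reads_bed(chip, paths["chip_bed"])
    write_reads_bed(control, paths["control_bed"])
    with open(paths["truth_bed"], "w") as fh:
        for iv in fixture.truth:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    return paths
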