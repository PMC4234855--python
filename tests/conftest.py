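import numpy as np
import pytest

from peakscale.signal_io import GenomeTable
from peakscale.synthetic import (
    FixtureSpec,
    PlantedER,
    RepeatFamily,
    make_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    """A 1 Mbp fixture with punctate and broad planted regions plus a
    repeat family whose source sits inside a planted region."""
    return FixtureSpec(
        genome_length=1_000_000,
        chrom="synth1",
        planted_ers=(
            PlantedER(200_000, 200_500, 8.0, "peaked"),
            PlantedER(400_000, 410_000, 8.0, "rectangular"),
            PlantedER(700_000, 705_000, 8.0, "rectangular"),
        ),
        repeat_blocks=(
            RepeatFamily(source=(402_000, 403_000), copy_starts=(800_000, 900_000)),
        ),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    return make_genome(small_spec)


@pytest.fixture(scope="session")
def small_reads(small_spec):
    return simulate_reads(small_spec)


@pytest.fixture
def tiny_genome() -> GenomeTable:
    return GenomeTable([("chr1", 1000), ("chr2", 500)])
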