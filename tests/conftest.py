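import numpy as np
import pytest

from nrchip import (
    GenomeLayout,
    AlignmentRecord,
    Library,
    SimConfig,
    build_toy_genome,
)


@pytest.fixture
def tiny_layout():
    return GenomeLayout.from_arm_fraction([("chrA", 10_000), ("chrB", 12_000)], 0.25)


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured simulation: 2 x 200 kb chromosomes."""
    return SimConfig(
        chrom_lengths=[("chrI", 200_000), ("chrII", 200_000)],
        n_genes=40,
        n_target_genes=10,
        n_grh=3,
        n_grts=3,
        n_reads=20_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return build_toy_genome(small_config)


def random_library(rng: np.random.Generator, layout: GenomeLayout,
                   n_reads: int = 200, read_length: int = 50,
                   max_hits: int = 4) -> Library:
    """Random valid library with occasional multimappers (test helper)."""
    chroms = layout.chromosomes
    lengths = layout.chrom_lengths
    records = []
    for i in range(n_reads):
        n_hits = int(rng.integers(1, max_hits + 1)) if rng.random() < 0.2 else 1
        rid = f"t{i:05d}"
        for _ in range(n_hits):
            c = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, lengths[c] - read_length + 1))
            strand = "+" if rng.integers(2) else "-"
            records.append(AlignmentRecord(rid, c, start, strand, read_length, n_hits))
    return Library(records)
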