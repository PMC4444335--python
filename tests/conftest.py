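import numpy as np
import pytest

from tamp_landscape.genome import GeneRecord, GenomeModel, random_genome


@pytest.fixture
def toy_genome() -> GenomeModel:
    """One chromosome, centromere at 50 kb, five abutting genes on the
    right arm and two on the left."""
    genes = [
        GeneRecord("L2", "chrT", 10_000, 12_000, "+"),
        GeneRecord("L1", "chrT", 30_000, 32_000, "-"),
        GeneRecord("A", "chrT", 60_000, 62_000, "+"),
        GeneRecord("B", "chrT", 62_000, 64_000, "+"),
        GeneRecord("C", "chrT", 64_000, 66_000, "-"),
        GeneRecord("D", "chrT", 66_000, 68_000, "+"),
        GeneRecord("E", "chrT", 68_000, 70_000, "+"),
    ]
    return GenomeModel(chromosomes=[("chrT", 100_000)],
                       centromeres={"chrT": 50_000}, genes=genes)


@pytest.fixture
def small_genome() -> GenomeModel:
    return random_genome(n_chromosomes=2, chrom_length=400_000,
                         n_genes_per_chrom=30, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
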