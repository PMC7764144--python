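import numpy as np
import pytest

from lncmode import GeneModel, GenomeAssembly, SimConfig, Transcript, simulate_dataset

BASES = np.array(list("ACGT"))


def random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_genome():
    """5 kb single chromosome with a fixed pseudo-random sequence."""
    r = np.random.default_rng(7)
    return GenomeAssembly({"chr1": random_seq(r, 5000)})


@pytest.fixture
def toy_gene(toy_genome):
    """+ strand two-exon gene: exons [0,200) and [700,1900), TSS at 0."""
    g = GeneModel(
        "gA",
        "chr1",
        "+",
        promoters=[("gA@p1", 0)],
        transcripts=[Transcript("gA.t1", "gA@p1", [(0, 200), (700, 1900)])],
    )
    g.validate()
    return g


@pytest.fixture
def toy_gene_minus(toy_genome):
    """- strand two-exon gene on the same chromosome, TSS at 4499."""
    g = GeneModel(
        "gB",
        "chr1",
        "-",
        promoters=[("gB@p1", 4499)],
        transcripts=[Transcript("gB.t1", "gB@p1", [(2600, 3800), (4300, 4500)])],
    )
    g.validate()
    return g


@pytest.fixture(scope="session")
def co_dataset():
    """One co-planted synthetic dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(seed=101, planted_mode="co", n_genes=25, n_true_targets=6))


@pytest.fixture(scope="session")
def post_dataset():
    return simulate_dataset(SimConfig(seed=102, planted_mode="post", n_genes=25, n_true_targets=6))
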