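import numpy as np
import pytest

from rqcsirna.annotation import GeneModel, sort_genes
from rqcsirna.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def tiny_genes():
    """Three genes on one chromosome: a tail-to-tail pair plus a lncRNA."""
    return sort_genes(
        [
            GeneModel("gA", "Chr1", 100, 1000, "+", "protein_coding", ((100, 400), (600, 1000))),
            GeneModel("gB", "Chr1", 1300, 2000, "-", "protein_coding", ((1300, 2000),)),
            GeneModel("gC", "Chr1", 30000, 31000, "+", "lncRNA", ((30000, 31000),)),
        ]
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic scenario (2,000 genes, 3+3 replicates), seed 1."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast scenario used for read-level (alignment-path) tests."""
    cfg = SyntheticConfig(n_genes=150, seed=7)
    return generate_dataset(cfg)


def random_reads(genes, n_reads, seed, multimapper_fraction=0.1):
    """Random reads: half placed inside gene bodies, half anywhere in the span."""
    from rqcsirna.counting import ReadAlignment

    rng = np.random.default_rng(seed)
    span = max(g.end for g in genes) + 5000
    reads = []
    for i in range(n_reads):
        length = int(rng.integers(15, 36))
        if rng.random() < 0.5:
            g = genes[rng.integers(0, len(genes))]
            start = int(rng.integers(max(g.start - 50, 0), g.end + 50))
        else:
            start = int(rng.integers(0, span - 36))
        n_hits = 3 if rng.random() < multimapper_fraction else 1
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(ReadAlignment(f"r{i}", genes[0].chrom, start, start + length, strand, n_hits))
    return reads
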