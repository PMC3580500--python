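import numpy as np
import pytest

from cpgchrom import synthetic as syn
from cpgchrom.annotations import GeneModel, GenomicInterval


@pytest.fixture(scope="session")
def small_data():
    """Miniature synthetic dataset shared by read/profile tests."""
    config = syn.SyntheticConfig(n_genes=60, seed=11, read_depth=60.0)
    return syn.make_genes(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_gene(gene_id="g", chrom="chr1", strand="+", tss=10_000, length=5000):
    end_ = tss + length if strand == "+" else tss - length
    return GeneModel(gene_id, chrom, strand, tss, end_)


@pytest.fixture()
def gene_factory():
    return make_gene
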