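import numpy as np
import pytest

from tftargets.intervals import GeneModel, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_gene(gene_id, chrom, tss, strand="+", length=1000):
    if strand == "+":
        iv = GenomicInterval(chrom, tss, tss + length, "+")
    else:
        iv = GenomicInterval(chrom, max(0, tss + 1 - length), tss + 1, "-")
    return GeneModel(gene_id=gene_id, interval=iv)


@pytest.fixture
def toy_genes():
    """Four genes on two chromosomes with well-separated TSSs."""
    return [
        make_gene("G001", "chr1", 10_000, "+"),
        make_gene("G002", "chr1", 200_000, "-"),
        make_gene("G003", "chr2", 50_000, "+"),
        make_gene("G004", "chr2", 400_000, "-"),
    ]
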