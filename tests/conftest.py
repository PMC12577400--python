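import numpy as np
import pytest

from coopreg.genome import GeneModel, Genome, GenomicInterval


@pytest.fixture
def small_genome() -> Genome:
    return Genome({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500, named=False):
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(
            GenomicInterval(chrom, start, start + length, name=f"iv{i}" if named else None)
        )
    return out


def random_genes(rng, n, chroms=("chr1", "chr2"), max_pos=100_000):
    genes = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos - 2000))
        length = int(rng.integers(500, 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i:04d}", chrom, strand, start, start + length))
    return genes
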