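import numpy as np
import pytest

from mircnv import ChromosomeModel, CnvRecord, MirnaGene


@pytest.fixture
def toy_genome():
    return [ChromosomeModel("1", 10_000), ChromosomeModel("2", 8_000)]


@pytest.fixture
def toy_genes():
    return [
        MirnaGene("mir-a", "1", 1_000, 1_099, "+"),
        MirnaGene("mir-b", "1", 4_990, 5_080, "-"),
        MirnaGene("mir-c", "1", 7_200, 7_290, "+"),
        MirnaGene("mir-d", "2", 2_000, 2_085, "+"),
    ]


@pytest.fixture
def toy_cnvs():
    return [
        CnvRecord("1", 100, 5_000, "Loss", ("p1",)),
        CnvRecord("1", 4_800, 6_000, "Loss", ("p2",)),
        CnvRecord("1", 9_000, 9_500, "Gain", ("p1",)),
        CnvRecord("2", 1_500, 2_050, "Gain", ("p3",)),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20140325)


def random_genes(rng, n, chrom_length, chrom="1", lo=80, hi=110):
    """Random (possibly overlapping) gene loci for oracle comparisons."""
    genes = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(1, chrom_length - length + 2))
        genes.append(MirnaGene(f"g{i}", chrom, start, start + length - 1))
    return genes
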