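import numpy as np
import pandas as pd
import pytest

from hitchcomb.datatypes import GenotypeTable, HaplotypePanel, make_variant_frame


def make_panel(alleles, positions=None, chrom="1", ids=None):
    """Build a HaplotypePanel from a raw 0/1 matrix (rows = haplotypes)."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    m = alleles.shape[1]
    positions = positions if positions is not None else np.arange(1, m + 1) * 1000
    ids = ids or [f"v{j}" for j in range(m)]
    maf = np.minimum(alleles.mean(axis=0), 1 - alleles.mean(axis=0))
    return HaplotypePanel(alleles, make_variant_frame(ids, chrom, positions, maf=maf))


def random_micro_panel(rng, max_hap=12, max_snps=10):
    """Small random panel for oracle comparisons (may contain fixed columns)."""
    n = int(rng.integers(2, max_hap + 1))
    m = int(rng.integers(2, max_snps + 1))
    alleles = (rng.random((n, m)) < rng.uniform(0.2, 0.8, m)).astype(np.uint8)
    return make_panel(alleles)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_panel():
    # 6 haplotypes x 7 SNPs, hand-checkable
    alleles = np.array(
        [
            [0, 0, 1, 0, 0, 1, 0],
            [0, 0, 1, 0, 0, 1, 0],
            [0, 1, 1, 1, 0, 0, 1],
            [1, 1, 0, 1, 1, 0, 1],
            [1, 0, 0, 1, 1, 0, 0],
            [0, 1, 0, 0, 1, 1, 0],
        ],
        dtype=np.uint8,
    )
    return make_panel(alleles)


@pytest.fixture
def toy_genotypes():
    codes = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 0, -1],
            [2, 0, 1, 0],
            [0, 2, 0, 1],
            [1, 0, 1, 2],
        ],
        dtype=np.int8,
    )
    variants = make_variant_frame(
        [f"s{j}" for j in range(4)], "2", [100, 200, 300, 400],
        allele_major=["A", "C", "G", "T"], allele_minor=["G", "T", "A", "C"],
    )
    return GenotypeTable(codes, variants, [f"b{i}" for i in range(5)])
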