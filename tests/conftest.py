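import numpy as np
import pandas as pd
import pytest

from imprintscan import AseConfig, MethylomeConfig, generate_ase, generate_methylome
from imprintscan.io_formats import GeneModel


@pytest.fixture(scope="session")
def small_ase():
    """Small reciprocal-cross dataset shared across read-only tests."""
    return generate_ase(AseConfig(n_genes=120), seed=7)


@pytest.fixture(scope="session")
def small_methylome():
    """Single-chromosome methylome with a few planted endosperm-hypo regions."""
    return generate_methylome(
        MethylomeConfig(chrom_length=60_000, n_random_regions=4), seed=11
    )


def make_gene(gene_id, start, end, chrom="Chr01", strand="+", biotype="coding"):
    return GeneModel(gene_id, chrom, start, end, strand, biotype)


def make_cytosines(rows):
    """rows: (chrom, pos, strand, context, meth, unmeth)"""
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "meth", "unmeth"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
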