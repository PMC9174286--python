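import numpy as np
import pytest

from paleopair.io import GenotypePanel, SnpPanel


def make_panel(alleles, chroms=None, positions=None):
    """Small hand-built SnpPanel from a list of (allele1, allele2) pairs."""
    n = len(alleles)
    chroms = np.array(chroms if chroms is not None else [1] * n, dtype=np.int64)
    positions = np.array(
        positions if positions is not None else 1000 * (np.arange(n) + 1),
        dtype=np.int64,
    )
    return SnpPanel(
        snp_id=np.array([f"rs{i}" for i in range(n)], dtype=object),
        chromosome=chroms,
        genetic_pos=positions * 1e-8,
        physical_pos=positions,
        allele1=np.array([a for a, _ in alleles], dtype=object),
        allele2=np.array([b for _, b in alleles], dtype=object),
    )


def make_geno(panel, individuals, matrix):
    return GenotypePanel(
        panel=panel,
        individuals=individuals,
        genotypes=np.asarray(matrix, dtype=np.int8),
    )


@pytest.fixture
def tiny_panel():
    return make_panel([("A", "C"), ("C", "T"), ("G", "T")])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
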