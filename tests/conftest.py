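import numpy as np
import pytest

from sgscan import GenotypeMatrix, VariantTable


def make_variants(M, spacing=1000, chrom="chr1", maf=0.01, start=1000):
    """Uniform variant grid helper used across the suite."""
    pos = start + np.arange(M, dtype=np.int64) * spacing
    return VariantTable(
        np.full(M, chrom, dtype=object),
        pos,
        np.array([f"v{i}" for i in range(M)], dtype=object),
        np.full(M, maf, dtype=float),
    )


def make_matrix(codes, spacing=1000, chrom="chr1", maf=0.01):
    """GenotypeMatrix from a (n_individuals, n_variants) code array."""
    codes = np.asarray(codes, dtype=np.int8)
    vt = make_variants(codes.shape[1], spacing=spacing, chrom=chrom, maf=maf)
    individuals = [f"s{i}" for i in range(codes.shape[0])]
    return GenotypeMatrix(vt, individuals, codes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
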