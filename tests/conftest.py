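import numpy as np
import pytest

from invscan import GenomicInterval, GenotypeMatrix


def make_gm(dosage, pos=None, chrom="chr1", sample_ids=None):
    """Small genotype matrix from a dosage array (samples x variants)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(
        sample_ids,
        np.array([chrom] * m, dtype=object),
        np.asarray(pos, dtype=np.int64),
        np.array(["A"] * m, dtype=object),
        np.array(["G"] * m, dtype=object),
        dosage,
    )


@pytest.fixture
def gm_factory():
    return make_gm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
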