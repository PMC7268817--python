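import numpy as np
import pytest

from ihtglm.genotypes import MISSING, GenotypeMatrix


def dense_standardized(G):
    """Dense float64 standardized genotype matrix (the oracle)."""
    counts = G.decode().astype(float)
    assert not np.any(counts == MISSING)
    scale = G.scale
    inv = np.zeros_like(scale)
    inv[scale > 0] = 1.0 / scale[scale > 0]
    return (counts - 2.0 * G.maf) * inv


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def random_genotypes(rng, n, p, missing_frac=0.0):
    maf = rng.uniform(0.05, 0.5, size=p)
    counts = rng.binomial(2, maf, size=(n, p)).astype(np.uint8)
    if missing_frac:
        mask = rng.random((n, p)) < missing_frac
        counts[mask] = MISSING
    return GenotypeMatrix.from_counts(counts)
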