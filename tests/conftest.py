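import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from epicolony.data_io import GenotypeDataset
from epicolony.simulator import model_registry


@pytest.fixture(scope="session")
def models():
    return model_registry()


@pytest.fixture
def tiny_dataset():
    """4 samples, 2 SNPs: one sample per (x, z, y) cell of a 2x2x2 layout."""
    return GenotypeDataset(
        genotypes=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
        phenotype=np.array([0, 0, 1, 1]),
        snp_ids=("S1", "S2"),
    )


def random_count_tensor(rng, allow_empty_slices=True):
    """A random nonnegative integer count tensor (nx, nz, 2) with n >= 1."""
    nx = rng.integers(2, 4)
    nz = rng.integers(2, 4)
    while True:
        c = rng.integers(0, 20, size=(nx, nz, 2))
        if c.sum() >= 1:
            return c.astype(np.float64)


def random_dataset(rng, n_samples=30, n_snps=4):
    """A random valid dataset (both phenotype classes guaranteed)."""
    g = rng.integers(0, 3, size=(n_samples, n_snps))
    y = rng.integers(0, 2, size=n_samples)
    y[0], y[1] = 0, 1
    return GenotypeDataset(
        genotypes=g,
        phenotype=y,
        snp_ids=tuple(f"S{i}" for i in range(n_snps)),
    )
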