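import numpy as np
import pytest

from attnmap.genotypes import CrossSimConfig, GenotypeMatrix, simulate_cross_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """50 individuals x 10 independent loci."""
    return simulate_cross_genotypes(CrossSimConfig(50, 10, 1, 0.5, seed=7))


@pytest.fixture
def random_genotypes(rng):
    """Factory for random +/-1 genotype matrices."""
    def make(n, L):
        values = rng.integers(0, 2, size=(n, L)) * 2 - 1
        return GenotypeMatrix(values, [f"l{j}" for j in range(L)])
    return make
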