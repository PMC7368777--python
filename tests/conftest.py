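import numpy as np
import pytest

from chromloop import SimConfig, make_genome


@pytest.fixture(scope="session")
def truth():
    """Default synthetic truth, shared across the suite (read-only)."""
    return make_genome(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_truth():
    """A smaller single-chromosome truth for cheap targeted tests."""
    return make_genome(SimConfig(n_chroms=1, chrom_length=200_000, n_tads=2,
                                 n_motifs=20, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
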