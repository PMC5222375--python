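import numpy as np
import pytest

from tetrags import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-genotype, 300-marker dataset shared by read-only tests."""
    cfg = SimConfig(n_genotypes=60, n_markers=300, seed=11, mean_depth=20)
    genos, rc, phenos, truth = simulate_dataset(cfg)
    return cfg, genos, rc, phenos, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
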