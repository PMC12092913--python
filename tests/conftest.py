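import numpy as np
import pytest

from lousescan import DesignConfig, SelectionRegime, sample_sequencing, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """One compact simulated experiment shared by read-only tests."""
    return simulate_experiment(
        DesignConfig(),
        SelectionRegime(s=0.1, n_trait_loci=8, ne=200, direction="darker"),
        seed=11,
        n_sites=400,
    )


@pytest.fixture(scope="session")
def small_seq(small_sim):
    return sample_sequencing(small_sim, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
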