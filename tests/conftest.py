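import numpy as np
import pytest

from regland.counts import size_factors, vst
from regland.simulate import SimulationConfig, simulate_accessibility


@pytest.fixture(scope="session")
def small_sim():
    """A compact planted-pattern dataset shared across read-only tests."""
    cfg = SimulationConfig(seed=11, n_elements=600)
    peaks, counts, samples, truth = simulate_accessibility(cfg)
    return cfg, peaks, counts, samples, truth


@pytest.fixture(scope="session")
def small_norm(small_sim):
    _cfg, _peaks, counts, _samples, _truth = small_sim
    sf = size_factors(counts)
    return vst(counts, sf), sf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
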