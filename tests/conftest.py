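import numpy as np
import pytest

from radhap.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A compact simulated RAD data set shared by pipeline-level tests."""
    out = tmp_path_factory.mktemp("simdata")
    config = SimulationConfig(n_taxa=6, n_loci=150, seed=11)
    truth = simulate_dataset(config, out)
    return truth, out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
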