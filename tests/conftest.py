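import numpy as np
import pytest

from wingmorph import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully featured simulated world shared across tests:
    8 species x 4 specimens, moderate habitat effect, both wings rendered."""
    cfg = SimulationConfig(n_species=8, n_per_species=4,
                           habitat_effect_size=0.02, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def forewing_sample(small_dataset):
    ds = small_dataset
    return ds.configurations["forewing"], ds.labels["forewing"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
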