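import pytest

from erfsalt.family import mine_family
from erfsalt.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def config():
    """Default study conditions, fixed seed."""
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(config):
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free limit: deterministic counts and phenotype means."""
    return simulate_dataset(SimConfig(seed=2, noise_sd=0))


@pytest.fixture(scope="session")
def mining(dataset):
    return mine_family(dataset.genome.proteins, dataset.genome.annotation)
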