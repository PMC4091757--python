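import pytest

from mircons import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def bundle():
    """A mid-sized synthetic fixture bundle shared across test modules."""
    return simulate_dataset(SimConfig(seed=11, n_families=12))


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_families=12)
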