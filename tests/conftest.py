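import numpy as np
import pytest

from finchnet.synthetic import ColonyConfig, generate_colony, simulate_visit_stream


@pytest.fixture(scope="session")
def small_config():
    """A reduced colony (2 aviaries x 3 families, 3 days) for fast unit tests."""
    return ColonyConfig(
        seed=7, n_days=3, families_per_aviary=(3, 3), event_rate=8.0,
        brood_size_range=(2, 3),
    )


@pytest.fixture(scope="session")
def small_colony(small_config):
    return generate_colony(small_config)


@pytest.fixture(scope="session")
def small_stream(small_colony, small_config):
    return simulate_visit_stream(small_colony, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
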