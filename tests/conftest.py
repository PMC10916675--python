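import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from epidiet.intervals import GenomeDescription
from epidiet.simulate import SimulationConfig, make_toy_genome


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study configuration shared by pipeline-level tests."""
    return SimulationConfig(seed=11, n_cells_per_condition=400, background_reads=5000)


@pytest.fixture(scope="session")
def toy_genome(small_config):
    return make_toy_genome(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
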