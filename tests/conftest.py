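import numpy as np
import pytest

from nextpbm.probe_design import SeedSite
from nextpbm.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled study conditions for fast unit tests; acceptance tests
    use the full set sizes."""
    return SimulationConfig(
        rng_seed=11, n_canonical=300, n_composite=40, n_background=100
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture
def eice_seed():
    """A composite element: GGAA core at offset 4, GAAAC half-site at 10."""
    return SeedSite("eice1", "ACTGGGAATCGAAACTGCAT", category_label="composite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
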