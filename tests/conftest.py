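import numpy as np
import pytest

import fiveaday as fd
from fiveaday import experiments as ex


@pytest.fixture(scope="session")
def profiles():
    return fd.load_default_profiles()


@pytest.fixture(scope="session")
def small_region():
    """10x10 toy region with 2000 agents; shared read-only across tests."""
    return fd.generate_region(
        fd.ToyRegionSpec(width=10, height=10, n_agents=2000, seed=3)
    )


@pytest.fixture(scope="session")
def small_engine(small_region):
    return ex.ScenarioEngine(ex.PopulationInputs.from_toy_region(small_region))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def binom_bound99(p: float, n: int) -> float:
    """Half-width of the 99% normal bound on a binomial proportion."""
    return 2.576 * np.sqrt(p * (1 - p) / n)
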