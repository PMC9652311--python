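import numpy as np
import pytest

from coalt.simulate import SimulationConfig, make_atlas, make_effects


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def atlas(config):
    return make_atlas(config)


@pytest.fixture(scope="session")
def effects(atlas, config):
    return make_effects(atlas, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
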