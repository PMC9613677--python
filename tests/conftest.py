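import numpy as np
import pytest
from hypothesis import settings

from pbftsim import SimulationConfig, TransportMedia, build_geometry

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=12345)


@pytest.fixture(scope="session")
def default_geometry(default_config):
    return build_geometry(default_config)


@pytest.fixture(scope="session")
def small_config():
    # 3x3 array keeps a cell centred on the beam axis
    return SimulationConfig(n=3, seed=99)


@pytest.fixture(scope="session")
def small_geometry(small_config):
    return build_geometry(small_config)


@pytest.fixture(scope="session")
def default_media(default_config):
    return TransportMedia(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
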