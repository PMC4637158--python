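import numpy as np
import pytest

from fibrosim.microstructure import build_template, tile_template
from fibrosim.discrete import reduce_to_network
from fibrosim.ionic import BondarenkoModel, SurrogateModel


@pytest.fixture(scope="session")
def unit_mesh():
    return build_template()


@pytest.fixture(scope="session")
def unit_net(unit_mesh):
    return reduce_to_network(unit_mesh, wrap=True)


@pytest.fixture(scope="session")
def strip_mesh(unit_mesh):
    """Homogeneous 4x1-unit strip (1920 x 144 um)."""
    return tile_template(unit_mesh, 4, 1)


@pytest.fixture(scope="session")
def strip_net(strip_mesh):
    return reduce_to_network(strip_mesh)


@pytest.fixture(scope="session")
def surrogate():
    return SurrogateModel()


@pytest.fixture(scope="session")
def bondarenko():
    return BondarenkoModel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
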