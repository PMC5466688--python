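import numpy as np
import pytest

from axdt.forward_model import Geometry, WeightModel
from axdt.sphere import hemisphere, load_tdesign_56


@pytest.fixture(scope="session")
def tdesign():
    return load_tdesign_56()


@pytest.fixture(scope="session")
def hemi(tdesign):
    return hemisphere(tdesign)


@pytest.fixture(scope="session")
def desk_geometry():
    """Small cubic volume / square detector used throughout the tests."""
    return Geometry((32, 32, 32), 1.0, (48, 48), 1.0)


@pytest.fixture(scope="session")
def model():
    return WeightModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
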