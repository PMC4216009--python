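import numpy as np
import pytest

from convef.edgemap import VectorField, edge_map
from convef.fixtures import ShapeSpec, make_shape_image


@pytest.fixture(scope="session")
def ushape():
    """Clean 64x64 U-shape image with ground truth."""
    return make_shape_image(ShapeSpec(family="ushape"))


@pytest.fixture(scope="session")
def ushape_edgemap(ushape):
    img, _ = ushape
    return edge_map(img, sigma=0, mode="magnitude")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def zero_field():
    z = np.zeros((64, 64))
    return VectorField(z, z.copy())
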