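import numpy as np
import pytest

from gliaquant import phantom as ph
from gliaquant import quantify as qt
from gliaquant.volume_io import VolumetricImage


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_stack(rng):
    data = rng.integers(0, 200, size=(5, 8, 8)).astype(np.uint16)
    return VolumetricImage(data, (0.5, 0.5, 1.0), name="small")


@pytest.fixture(scope="session")
def cylinder_mask():
    # slim aspect: blunt-end erosion during thinning stays well under 10%
    return ph.make_cylinder_mask((15, 95, 15), (0.5, 0.5, 0.5),
                                 radius_um=2.5, height_um=40.0)


@pytest.fixture(scope="session")
def cylinder_skeleton(cylinder_mask):
    return qt.skeletonize_3d(cylinder_mask)


@pytest.fixture(scope="session")
def y_mask():
    return ph.make_y_mask()


@pytest.fixture(scope="session")
def y_skeleton(y_mask):
    return qt.skeletonize_3d(y_mask)


@pytest.fixture(scope="session")
def default_phantom():
    spec = ph.PhantomSpec()
    image, truth = ph.generate_glia_phantom(spec)
    return spec, image, truth
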