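import numpy as np
import pytest

from theradose.grids import ScalarVolume, VoxelGrid
from theradose.nuclides import get_nuclide
from theradose.phantom import PhantomConfig, add_imaging_noise, build_phantom


@pytest.fixture(scope="session")
def lu():
    return get_nuclide("Lu-177")


@pytest.fixture(scope="session")
def zr():
    return get_nuclide("Zr-89")


@pytest.fixture(scope="session")
def phantom_default():
    """Noiseless default phantom; session-scoped because rasterization is the
    slow part and the study object is treated as read-only by tests."""
    return build_phantom()


@pytest.fixture(scope="session")
def phantom_noisy(phantom_default):
    return add_imaging_noise(phantom_default, psf_sigma_mm=4.0, noise_cv=0.03, seed=1)


@pytest.fixture
def uniform_water():
    """16³ uniform 1 MBq/mL activity in unit-density water, 4 mm voxels."""
    g = VoxelGrid((16, 16, 16), (4.0, 4.0, 4.0))
    act = ScalarVolume(g, np.full(g.shape, 1e6), "Bq/mL", timestamp=4.0, nuclide_tag="Lu-177")
    den = ScalarVolume(g, np.ones(g.shape), "g/cm3")
    return act, den
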