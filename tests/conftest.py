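import numpy as np
import pytest

from tcbc.core import select_target_roi
from tcbc.geometry import ImageVolume, ROIMask
from tcbc.petsim import PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def small_cfg() -> PhantomConfig:
    """48^3 phantom, 4 mm voxels: fast enough for per-test use."""
    return PhantomConfig(shape=(48, 48, 48), voxel_size_mm=4.0, seed=3)


@pytest.fixture(scope="session")
def small_phantom(small_cfg):
    return make_phantom(small_cfg)


@pytest.fixture(scope="session")
def mid_phantom():
    """64^3 phantom, 3 mm voxels: used by registration tests."""
    return make_phantom(PhantomConfig(shape=(64, 64, 64), voxel_size_mm=3.0,
                                      seed=5))


@pytest.fixture(scope="session")
def wm_mask(small_phantom) -> ROIMask:
    _, _, seg = small_phantom
    return select_target_roi(seg, [2, 41])


@pytest.fixture()
def gaussian_blob() -> ImageVolume:
    """Smooth volume on an anisotropic grid for resampling tests."""
    n = 32
    x, y, z = np.meshgrid(*(np.arange(n) - (n - 1) / 2,) * 3, indexing="ij")
    data = np.exp(-(x**2 + y**2 + z**2) / (2 * 10.0**2))
    affine = np.diag([2.0, 2.5, 3.0, 1.0])
    affine[:3, 3] = -(n - 1) / 2 * np.array([2.0, 2.5, 3.0])
    return ImageVolume(data, affine)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
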