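import numpy as np
import pytest

from tsquant.geometry import ImageStack, default_geometry
from tsquant.simulate import NoiseModel, PSFModel, add_gaussian_spot

# default PSF in voxel units (107.5 nm xy pixel, 300 nm z-step)
SXY = 100.0 / 107.5
SZ = 350.0 / 300.0
GAUSS_NORM = (2.0 * np.pi) ** 1.5


@pytest.fixture
def psf():
    return PSFModel()


@pytest.fixture
def noise_off():
    return NoiseModel(background=100.0, gain=0.0, read_sigma=0.0)


@pytest.fixture
def small_geometry():
    return default_geometry((11, 96, 96))


def render_spots(shape, centers, integrals, background=100.0, sigma_xy=SXY, sigma_z=SZ):
    """Noiseless stack with Gaussian spots of given integrated intensities."""
    data = np.full(shape, float(background))
    for c, i in zip(centers, integrals):
        add_gaussian_spot(data, c, i, sigma_xy, sigma_z)
    return ImageStack(data)


def amp_to_integral(amplitude, sigma_xy=SXY, sigma_z=SZ):
    return amplitude * GAUSS_NORM * sigma_xy**2 * sigma_z
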