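import numpy as np
import pytest

from qustex.data_model import AcquisitionGeometry, PixelGrid
from qustex import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_geometry():
    """16 mm deep x 12.8 mm wide frame at 20 MHz sampling, 64 lines."""
    return AcquisitionGeometry(
        sampling_frequency=20e6, speed_of_sound=1540.0, center_frequency=6.5e6,
        analysis_band=(3.0, 8.0), n_lines=64, lateral_fov=0.0128, axial_samples=416)


@pytest.fixture(scope="session")
def paper_geometry():
    """Acquisition settings of the clinical system (40 MHz, 512 lines, 6 cm FOV)."""
    return AcquisitionGeometry(
        sampling_frequency=40e6, speed_of_sound=1540.0, center_frequency=6.5e6,
        analysis_band=(3.0, 8.0), n_lines=512, lateral_fov=0.06, axial_samples=2078)


@pytest.fixture(scope="session")
def reference_phantom(small_geometry):
    return simulate.simulate_reference_frames(small_geometry, seed=777, n_frames=2)


@pytest.fixture
def fine_grid():
    return PixelGrid(origin_mm=(0.05, 0.05), spacing_mm=(0.1, 0.1), shape=(220, 220))


def random_masked_levels(rng, shape=(6, 6), n_levels=4, mask_p=0.75):
    """Random quantized image with a random mask (0 marks unmasked)."""
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask[0, 0] = True
    levels = np.where(mask, levels, 0).astype(np.int32)
    return levels, mask
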