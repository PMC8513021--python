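import numpy as np
import pytest

from pepperseg.optics import SpectralCube, TransmittanceCurve, gaussian_csr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube(rng):
    """Random 8x8x20 radiance cube on a visible band grid."""
    wl = np.linspace(400, 700, 20)
    return SpectralCube(rng.uniform(0.05, 1.0, (8, 8, 20)), wl)


@pytest.fixture
def small_filter(rng, small_cube):
    return TransmittanceCurve(rng.uniform(0.1, 1.0, 20), small_cube.wavelengths)


@pytest.fixture
def small_csr(small_cube):
    return gaussian_csr(small_cube.wavelengths)


@pytest.fixture
def tiny_scenes():
    """Two tiny labeled scenes (32x32, 12 bands) for fast training tests."""
    from pepperseg.simulate import SceneSpec, simulate_dataset

    spec = SceneSpec(n_bands=12, height=32, width=32, contrast_delta=0.3,
                     axis_range=(4.0, 8.0), seed=7)
    return simulate_dataset(2, 1, 1, spec, seed=7)
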