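import numpy as np
import pytest

from hsimargin.hypercube_io import build_band_grid
from hsimargin.synthetic_scene import SceneSpec, SpectralModel, generate_patient


@pytest.fixture(scope="session")
def grid91():
    """Full reflectance grid: 450-900 nm, 5 nm steps."""
    return build_band_grid(450, 900, 5)


@pytest.fixture(scope="session")
def tiny_grid():
    """9-band grid for fast classifier tests."""
    return build_band_grid(450, 530, 10)


@pytest.fixture(scope="session")
def tiny_spec(tiny_grid):
    """Small, fast phantom: 40x40 px, 9 bands."""
    return SceneSpec(image_size=(40, 40), grid=tiny_grid)


@pytest.fixture(scope="session")
def tiny_patient(tiny_spec):
    return generate_patient(tiny_spec, "P000", seed=11)


@pytest.fixture(scope="session")
def small_spec91():
    """Moderate phantom on the full 91-band grid (64x64 px)."""
    return SceneSpec(image_size=(64, 64))


@pytest.fixture(scope="session")
def small_patient91(small_spec91):
    return generate_patient(small_spec91, "P000", seed=5)
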