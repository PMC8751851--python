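import numpy as np
import pytest

from mreyetrack.geometry import Ellipsoid, build_eye_model
from mreyetrack.ngm import NGMConfig
from mreyetrack.synthetic_data import (
    IntensityModel,
    default_eye_model,
    render_volume,
)


@pytest.fixture(scope="session")
def eye_model():
    """Population-mean eye model centered at the origin."""
    return default_eye_model()


@pytest.fixture(scope="session")
def tilted_eye_model():
    """An asymmetric model exercising all rotations."""
    sclera = Ellipsoid((0.5, -0.3, 0.2), (6.0, -3.0, 4.0), (11.6, 12.5, 11.9))
    return build_eye_model(
        sclera, (7.6, 7.6, 7.6), (8.0, 0.0, -5.0), (4.0, 1.8, 4.0),
        (6.0, 0.0, -4.0)
    )


@pytest.fixture(scope="session")
def noisefree_intensity():
    return IntensityModel(inside_sd=0.0, outside_sd=0.0, lens_sd=0.0)


@pytest.fixture(scope="session")
def noisefree_volume(eye_model, noisefree_intensity):
    """Noise-free rendered T2-like volume of the default eye."""
    return render_volume(eye_model, rng=0, intensity=noisefree_intensity)


@pytest.fixture(scope="session")
def noisy_volume(eye_model):
    return render_volume(eye_model, rng=0)


@pytest.fixture()
def fast_config():
    """Reduced-budget NGM configuration for smoke tests."""
    return NGMConfig(n_surface_points=600, budget=1500)
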