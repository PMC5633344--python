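import numpy as np
import pytest

from pexflux import synthetic
from pexflux.io import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_noise():
    """Noise model with no camera background and no measurement noise."""
    return synthetic.NoiseModel(
        background_mean=0.0, background_sd=0.0, density_noise_scale=0.0
    )


@pytest.fixture
def sphere_truth():
    """Five well-separated spheres with default noise statistics."""
    spec = synthetic.GeometrySpec(seed=7, n_peroxisomes=5)
    return synthetic.generate_geometry(spec)


@pytest.fixture
def empty_truth():
    """A volume with no objects (pure background when rendered)."""
    spec = synthetic.GeometrySpec(seed=0, n_peroxisomes=0, shape=(24, 64, 64))
    return synthetic.generate_geometry(spec)


def make_sphere_stack(shape=(24, 64, 64), center=(12, 32, 32), radius=4.0, value=200.0):
    """A single bright sphere on a zero background (no noise)."""
    zz, yy, xx = np.indices(shape)
    dist2 = (
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    data = np.where(dist2 <= radius**2, value, 0.0)
    return ImageStack(data, channel="test")
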