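import numpy as np
import pytest

from melrad.radiomics.discretize import discretize_volume
from melrad.synthetic import Lesion, PhantomSpec, generate_phantom


def random_region(rng, shape=(4, 4, 4), bin_width=0.25, fill=0.7):
    """A random discretized region with a random (non-empty) mask."""
    image = rng.random(shape)
    mask = rng.random(shape) < fill
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    return discretize_volume(image, mask, bin_width)


def region_from_levels(levels, mask=None):
    """Build a DiscretizedRegion with prescribed integer gray levels."""
    levels = np.asarray(levels)
    if mask is None:
        mask = np.ones(levels.shape, dtype=bool)
    # unit bin width maps integer intensities straight onto themselves
    return discretize_volume(levels.astype(float) + 0.5, mask, 1.0)


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(
        shape=(48, 40, 40),
        spacing=(1.0, 1.0, 1.0),
        liver_center=(20.0, 20.0, 20.0),
        liver_mean=2.0,
        liver_sd=0.0,
        lesions=(Lesion(center=(41.0, 20.0, 20.0), radius=5.0, suv=8.0),),
        noise_sd=0.0,
        seed=0,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def textured_phantom():
    spec = PhantomSpec(seed=3)
    return generate_phantom(spec)
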