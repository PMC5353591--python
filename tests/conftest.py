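import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from vqlung.grid import BinaryMask, ImageGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20200101)


@pytest.fixture
def random_volumes(rng):
    """An aligned (dose, mask) pair on an 8x8x8 grid with ~half voxels set."""
    shape = (8, 8, 8)
    dose = ImageGrid(rng.uniform(0, 40, shape), spacing=(2.0, 2.0, 3.0))
    mask = BinaryMask(rng.random(shape) < 0.5, spacing=(2.0, 2.0, 3.0))
    return dose, mask
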