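import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from temporalis.imaging_io import BinaryMask
from temporalis.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom_spec():
    """64 px phantoms at 2 mm spacing — the desk-scale study condition."""
    return PhantomSpec(image_size=64, pixel_spacing_mm=2.0, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return generate_phantom(small_phantom_spec, 0)


def make_mask(coords, shape=(8, 8), spacing=(1.0, 1.0)):
    arr = np.zeros(shape, dtype=np.uint8)
    for (i, j) in coords:
        arr[i, j] = 1
    return BinaryMask(labels=arr, spacing=spacing)


@pytest.fixture
def mask_factory():
    return make_mask


def random_mask_pair(rng, shape=(16, 16), p_fg=0.3, spacing=(1.0, 1.0)):
    a = (rng.random(shape) < p_fg).astype(np.uint8)
    b = (rng.random(shape) < p_fg).astype(np.uint8)
    return BinaryMask(labels=a, spacing=spacing), BinaryMask(labels=b, spacing=spacing)
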