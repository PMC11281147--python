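import numpy as np
import pytest

from trapaug import AnnotatedImage, Box, SynthConfig, generate_trap_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Synthetic trap config small enough for fast per-test generation."""
    return SynthConfig(image_size=96, n_insects=(3, 6), insect_axes=(2.0, 6.0), seed=11)


@pytest.fixture
def trap_image(small_cfg):
    return generate_trap_image(small_cfg, np.random.default_rng(42), id="fixture_trap")


def make_image(value=128, size=32, boxes=(), id="img"):
    """Uniform test raster with optional boxes."""
    arr = np.full((size, size, 3), value, dtype=np.uint8)
    return AnnotatedImage(arr, list(boxes), id=id)


@pytest.fixture
def centered_box():
    return Box(0, 0.5, 0.5, 0.2, 0.2)
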