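import numpy as np
import pytest

from xdream.generators import LinearGenerator, PixelGenerator
from xdream.targets import MatchedFilterUnit, build_gabor_template


@pytest.fixture
def pixel_gen():
    """Pixel generator on 8x8 grayscale images (d = 64)."""
    return PixelGenerator((8, 8, 1))


@pytest.fixture
def linear_gen():
    """Small linear generator: 8 latent dims driving an 8x8 image."""
    return LinearGenerator(d=8, image_shape=(8, 8, 1), seed=11)


@pytest.fixture
def gabor_unit():
    """Matched-filter unit whose optimum (score 1) is a known Gabor patch."""
    template = build_gabor_template(4.0, 0.0, 0.0, 3.0, (8, 8, 1))
    return MatchedFilterUnit(template, name="gabor8")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
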