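import numpy as np
import pytest

from profilex import FixtureSpec, GrayImage, NoiseSpec, add_gaussian_noise, make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def blob_image():
    """A clean 128x128 blob-field scene on the unit interval."""
    return make_fixture(FixtureSpec("blob-field", 128, 128, seed=7))


@pytest.fixture
def noisy_blob_8bit():
    """A mean-0.9 degraded blob field on the 0-255 display scale."""
    img = make_fixture(FixtureSpec("blob-field", 128, 128, seed=7))
    noisy, _ = add_gaussian_noise(img, NoiseSpec(mean=0.9, variance=0.01, seed=7))
    return GrayImage(noisy.pixels * 255.0, value_domain="display-8bit")
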