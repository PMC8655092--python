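import numpy as np
import pytest

from fundus_wssh.types import RasterImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_gray(rng):
    """A random 8-bit grayscale image as a RasterImage."""
    return RasterImage(
        rng.integers(0, 256, size=(8, 8)).astype(np.float64), color_space="GRAY"
    )


@pytest.fixture
def random_rgb(rng):
    return RasterImage(
        rng.integers(0, 256, size=(16, 16, 3)).astype(np.float64), color_space="RGB"
    )


@pytest.fixture(scope="session")
def synthetic_image_and_truth():
    """One seeded 256 px synthetic fundus with ground truth (session-cached)."""
    from fundus_wssh.synthetic import generate_fundus

    return generate_fundus(seed=42, grade=3)
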