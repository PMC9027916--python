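import numpy as np
import pytest

from ettloc import phantom
from ettloc.io import KeypointSet


@pytest.fixture(scope="session")
def small_phantoms():
    """A dozen rendered phantoms at the default 128x128 test geometry."""
    return phantom.generate(phantom.PhantomConfig(n_images=12, seed=7))


@pytest.fixture(scope="session")
def tiny_phantoms_64():
    """Small 64x64 phantoms for fast network smoke tests."""
    cfg = phantom.PhantomConfig(
        image_size=(64, 64), pixel_spacing=(1.6, 1.6), n_images=10, seed=3
    )
    return phantom.generate(cfg)


@pytest.fixture()
def sample_keypoints():
    return KeypointSet(
        tube_end=(64.0, 40.0),
        carina=(63.0, 95.0),
        clavicle_left=(38.0, 25.0),
        clavicle_right=(90.0, 27.0),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
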