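import numpy as np
import pytest

import speckleid as sk
from speckleid.simulate import OpticalConfig, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def catalog():
    return sk.default_catalog()


@pytest.fixture(scope="session")
def optical_512():
    return OpticalConfig(frame_height_px=512, frame_width_px=512)


@pytest.fixture(scope="session")
def optical_128():
    return OpticalConfig(frame_height_px=128, frame_width_px=128)


@pytest.fixture(scope="session")
def speckle_frame_224(optical_512):
    """One quantized 224x224 speckle crop for generic feature tests."""
    rng = np.random.default_rng(99)
    img = sk.simulate_frame(0.5, SimConfig(), optical_512, rng)
    return img[:224, :224]


def random_images(n, shape=(16, 16), levels=16, seed=0):
    """Random low-level-count test images (keeps brute-force oracles fast)."""
    rng = np.random.default_rng(seed)
    step = 256 // levels
    return [rng.integers(0, levels, size=shape).astype(np.uint8) * step
            for _ in range(n)]
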