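import numpy as np
import pytest

from finpose.codec import CodecConfig
from finpose.nn.model import NetworkConfig
from finpose.synthetic import SceneRanges, generate_dataset


@pytest.fixture(scope="session")
def tiny_cfg() -> NetworkConfig:
    """Small isotropic network used throughout: 64x64 input, M=8, N=4, K=1."""
    return NetworkConfig(H=64, W=64, I=1, M=8, O=1, N=4)


@pytest.fixture(scope="session")
def tiny_dataset():
    """64x64 synthetic single-keypoint dataset shared by training tests."""
    return generate_dataset(32, 1, SceneRanges(frame_size=(64, 64)), seed=7)


@pytest.fixture(scope="session")
def seven_kp_dataset():
    """Small 7-keypoint dataset at 96x96."""
    return generate_dataset(12, 7, SceneRanges(frame_size=(96, 96)), seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
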