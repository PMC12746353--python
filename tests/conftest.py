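import numpy as np
import pytest

from motionsampling import make_shepp_logan_3d
from motionsampling.motion import MotionTrack


@pytest.fixture(scope="session")
def phantom16():
    return make_shepp_logan_3d(16)


@pytest.fixture(scope="session")
def phantom32():
    return make_shepp_logan_3d(32)


@pytest.fixture(scope="session")
def phantom64():
    return make_shepp_logan_3d(64)


def zero_track(n_readouts: int) -> MotionTrack:
    return MotionTrack(np.zeros((n_readouts, 3)), np.zeros((n_readouts, 3)))


def constant_track(n_readouts: int, rotations, translations=(0.0, 0.0, 0.0)) -> MotionTrack:
    return MotionTrack(
        np.tile(np.asarray(rotations, float), (n_readouts, 1)),
        np.tile(np.asarray(translations, float), (n_readouts, 1)),
    )
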