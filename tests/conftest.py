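import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def game_config():
    from cervigame import GameConfig

    return GameConfig()


def static_stream(duration_s=3.0, rate_hz=50.0, euler=(0.0, 0.0, 0.0)):
    """A noiseless IMU stream of a motionless head at the given YZX angles."""
    from cervigame import compose_yzx
    from cervigame.fusion import GRAVITY_WORLD, MAG_WORLD, ImuStream

    R = compose_yzx(euler).dcm
    n = int(duration_s * rate_hz) + 1
    t = np.arange(n) / rate_hz
    accel = np.tile(R.T @ GRAVITY_WORLD, (n, 1))
    mag = np.tile(R.T @ MAG_WORLD, (n, 1))
    return ImuStream.from_arrays(t, np.zeros((n, 3)), accel, mag)
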