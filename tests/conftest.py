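import numpy as np
import pytest

from gaitevents.core import IMURecording
from gaitevents.simulate import SimTrialConfig, simulate_trial, standard_fixture_suite


@pytest.fixture(scope="session")
def fixture_suite():
    """Standard test bed: 3 speeds x 3 foot-strike classes x 2 placements x 5 seeds."""
    return standard_fixture_suite()


@pytest.fixture(scope="session")
def shank_trial():
    return simulate_trial(SimTrialConfig(placement="shank", speed=4.0, seed=11))


@pytest.fixture(scope="session")
def sacrum_trial():
    return simulate_trial(SimTrialConfig(placement="sacrum", speed=4.0, seed=11))


@pytest.fixture
def still_recording():
    """1 s of a tilted, motionless sensor at 1000 Hz (gravity only)."""
    n, rate = 1000, 1000.0
    a0 = np.array([0.2, 0.9, 0.4])
    a0 /= np.linalg.norm(a0)
    return IMURecording(
        time=np.arange(n) / rate,
        accel=np.tile(a0[:, None], (1, n)),
        gyro=np.zeros((3, n)),
        rate_hz=rate,
    )
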