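import numpy as np
import pytest

from pairschool.kinematics import LocomotorParams, TrajectoryPair
from pairschool.simulator import SimConfig, simulate_pair


@pytest.fixture(scope="session")
def params() -> LocomotorParams:
    return LocomotorParams()


@pytest.fixture(scope="session")
def short_sim():
    """One 5-minute closed-loop run with full internals, shared across tests."""
    return simulate_pair(SimConfig(duration=300.0, seed=7), full_output=True)


def make_linear_pair(n=30, v1=(5.0, 0.0), v2=(5.0, 0.0), offset=(5.0, 0.0),
                     frame_rate=30.0) -> TrajectoryPair:
    """Two fish moving at constant velocity; fish 2 offset from fish 1."""
    t = np.arange(n) / frame_rate
    p1 = np.outer(t, np.asarray(v1))
    p2 = np.outer(t, np.asarray(v2)) + np.asarray(offset)
    return TrajectoryPair(times=t, positions=np.stack([p1, p2], axis=1),
                         frame_rate=frame_rate)
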