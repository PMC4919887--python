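import numpy as np
import pytest

from rafttrack import MembraneModelParams, Trajectory


@pytest.fixture(scope="session")
def tau():
    return 0.025


def make_track(xy, track_id=0, frames=None, frame_period=0.025):
    xy = np.asarray(xy, dtype=float)
    if frames is None:
        frames = np.arange(len(xy))
    return Trajectory(track_id=track_id, frames=frames, x=xy[:, 0], y=xy[:, 1],
                      frame_period=frame_period)


def random_walk_track(rng, n=100, D=0.1, tau=0.025, track_id=0):
    steps = rng.normal(0, np.sqrt(2 * D * tau), (n - 1, 2))
    pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return make_track(pos, track_id=track_id, frame_period=tau)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
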