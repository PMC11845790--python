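import numpy as np
import pytest

from tailflow.trajectory_io import tracks_from_arrays


def make_trackset(positions, frame_interval=2.0, tissue=None, embryo_id=""):
    """TrackSet from a (n_tracks, n_frames, 3) position array."""
    pos = np.asarray(positions, float)
    n, f = pos.shape[:2]
    ids = np.repeat(np.arange(n), f)
    frames = np.tile(np.arange(f), n)
    tis = None if tissue is None else list(np.repeat(tissue, f))
    return tracks_from_arrays(ids, frames, pos.reshape(-1, 3), frame_interval,
                              tissue=tis, embryo_id=embryo_id)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid9_static():
    """9 cells on a 3x3 grid (z=0), static over 5 frames."""
    xy = np.array([(x, y, 0.0) for x in (0.0, 10.0, 20.0) for y in (0.0, 10.0, 20.0)])
    pos = np.repeat(xy[:, None, :], 5, axis=1)
    return make_trackset(pos)


def rigid_motion_trackset(n_frames=16, frame_interval=2.0, seed=0):
    """A fixed random configuration translating rigidly frame by frame.

    Separation vectors are constant, so the vector-based MSRD is exactly zero.
    (A rigid rotation changes the orientation of separation vectors and is
    deliberately not included: the MSRD of a rotating solid is small but
    nonzero.)
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 50, (40, 3))
    shift = np.array([1.5, -0.7, 0.3]) * np.arange(n_frames)[:, None]
    pos = X[:, None, :] + shift[None, :, :]
    return make_trackset(pos, frame_interval)
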