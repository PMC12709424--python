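import numpy as np
import pytest

from loopdyn.traj import AtomRecord, Trajectory


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_trajectory():
    """3 atoms, 2 frames, convenient round numbers."""
    coords = np.array(
        [
            [[0.0, 0.0, 0.0], [3.0, 4.0, 0.0], [1.0, 1.0, 1.0]],
            [[0.5, 0.0, 0.0], [3.5, 4.0, 0.0], [1.5, 1.0, 1.0]],
        ]
    )
    meta = [
        AtomRecord(1, "GLY", "N"),
        AtomRecord(1, "GLY", "CA"),
        AtomRecord(2, "ALA", "CB"),
    ]
    return Trajectory(coords, meta, frame_interval=0.1)


def random_rigid_motion(rng):
    """A random proper rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix(), rng.normal(scale=10.0, size=3)


@pytest.fixture()
def two_state_model():
    """Simple 2-state reversible MSM, lag time 1 ns."""
    from loopdyn.msm import MarkovModel

    T = np.array([[0.9, 0.1], [0.1, 0.9]])
    return MarkovModel(T=T, pi=np.array([0.5, 0.5]), lag=1, frame_interval=1.0)
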