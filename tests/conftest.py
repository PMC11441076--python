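import numpy as np
import pytest

from neurofate import SessionCloud, SimilarityTransform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cloud(rng):
    """Random 200-point cloud in a 200 um box (no hard core — oracle fodder)."""
    xyz = rng.random((200, 3)) * 200.0
    return SessionCloud(
        xyz=xyz,
        ids=np.arange(200),
        tangle=np.zeros(200, bool),
        fiducial=np.zeros(200, bool),
        bounds=np.array([[0.0, 0.0, 0.0], [200.0, 200.0, 200.0]]),
        week=1,
    )


def make_cloud(xyz, week=1, bounds=None, tangle=None, fiducial=None, ids=None):
    xyz = np.asarray(xyz, float)
    n = len(xyz)
    if bounds is None:
        bounds = np.stack([xyz.min(axis=0) - 1, xyz.max(axis=0) + 1])
    return SessionCloud(
        xyz=xyz,
        ids=np.arange(n) if ids is None else ids,
        tangle=np.zeros(n, bool) if tangle is None else tangle,
        fiducial=np.zeros(n, bool) if fiducial is None else fiducial,
        bounds=bounds,
        week=week,
    )


def random_similarity(rng, max_angle_deg=30.0, scale_range=(0.8, 1.25), max_t=50.0):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    return SimilarityTransform(
        scale=rng.uniform(*scale_range),
        rotation=rot,
        translation=rng.uniform(-max_t, max_t, 3),
    )
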