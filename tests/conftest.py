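import numpy as np
import pytest
import trimesh

from dynifs.io_formats import BoneModel, MarkerTrajectorySet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def axis_angle(axis, theta: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


def full_surface_model(mesh: trimesh.Trimesh) -> BoneModel:
    v = np.asarray(mesh.vertices, float)
    return BoneModel(v, np.asarray(mesh.faces, np.int64), {}, {},
                     {"all": np.arange(v.shape[0])})


@pytest.fixture
def tetra_markers():
    """Static 4-marker cluster (regular-ish tetrahedron, mm scale)."""
    pts = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0],
                    [0.0, 100.0, 0.0], [0.0, 0.0, 100.0]])
    labels = ["m1", "m2", "m3", "m4"]
    pos = np.repeat(pts[None, :, :], 10, axis=0)
    return MarkerTrajectorySet(labels, pos, 100.0), dict(zip(labels, pts))
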