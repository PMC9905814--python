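"""Rigid point-set registration (Kabsch / SVD absolute orientation).

Given corresponded landmark sets P (imaging/neutral frame) and Q (lab
frame), find the proper rotation R and translation t minimizing
``sum_i || R p_i + t - q_i ||^2``.  The closed-form solution: centre both
sets, build the cross-covariance H = P' Q'^T, take its SVD, and set
R = V U^T with a determinant correction so R is never a reflection;
then t = -R mu_P + mu_Q.  Bone landmarks A are mapped into the lab frame
per capture frame as B = R A + t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LandmarkCorrespondence",
    "RigidTransform",
    "estimate_rigid_transform",
    "apply_transform",
    "compose",
    "invert",
    "rotation_angle_deg",
]

_ORTHO_TOL = 1e-9
_COLLINEAR_TOL = 1e-6


@dataclass(frozen=True)
class LandmarkCorrespondence:
    """Paired point sets: ``source`` (neutral/imaging frame, mm) and
    ``target`` (lab frame, mm), one row per landmark, same ordering."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        src = np.asarray(self.source, dtype=float)
        tgt = np.asarray(self.target, dtype=float)
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "target", tgt)
        if src.ndim != 2 or src.shape[1] != 3 or src.shape != tgt.shape:
            raise ValueError(
                f"source/target must be matching (N, 3) arrays, got "
                f"{src.shape} and {tgt.shape}"
            )
        if src.shape[0] < 3:
            raise ValueError("at least 3 point pairs are required")
        if not (np.isfinite(src).all() and np.isfinite(tgt).all()):
            raise ValueError("landmark coordinates must be finite")

    @property
    def n_points(self) -> int:
        return self.source.shape[0]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``rotation`` (3x3, det +1) and ``translation``
    (3-vector, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.isfinite(r).all() or not np.isfinite(t).all():
            raise ValueError("transform entries must be finite")
        if np.abs(r.T @ r - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation is a reflection (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def estimate_rigid_transform(corr: LandmarkCorrespondence) -> RigidTransform:
    """Least-squares rigid fit of ``corr.source`` onto ``corr.target``.

    Steps: centroids mu_P, mu_Q; decentred P', Q'; 3x3 cross-covariance
    H = P' Q'^T (column-vector convention); SVD H = U S V^T; R = V U^T with the last
    column of V negated when det(V U^T) < 0 (Kabsch reflection guard);
    t = -R mu_P + mu_Q.

    Raises
    ------
    ValueError
        If the source set is collinear (rotation under-determined).
    """
    p = corr.source
    q = corr.target
    mu_p = p.mean(axis=0)
    mu_q = q.mean(axis=0)
    p_c = p - mu_p
    q_c = q - mu_q

    sv = np.linalg.svd(p_c, compute_uv=False)
    if sv[1] <= _COLLINEAR_TOL * sv[0]:
        raise ValueError("source landmarks are collinear; rotation is under-determined")

    h = p_c.T @ q_c
    u, _, vt = np.linalg.svd(h)
    v = vt.T
    r = v @ u.T
    if np.linalg.det(r) < 0:
        v = v.copy()
        v[:, -1] *= -1.0
        r = v @ u.T
    t = -r @ mu_p + mu_q
    return RigidTransform(r, t)


def apply_transform(tf: RigidTransform, points: np.ndarray) -> np.ndarray:
    """Map points A (N, 3) to B = R A + t, rowwise."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 3:
        raise ValueError("points must have shape (..., 3)")
    out = pts @ tf.rotation.T + tf.translation
    return out[0] if single else out


def compose(tf1: RigidTransform, tf2: RigidTransform) -> RigidTransform:
    """Transform equal to applying ``tf2`` first, then ``tf1``."""
    return RigidTransform(
        tf1.rotation @ tf2.rotation,
        tf1.rotation @ tf2.translation + tf1.translation,
    )


def invert(tf: RigidTransform) -> RigidTransform:
    """Inverse transform: compose(tf, invert(tf)) is the identity."""
    r_inv = tf.rotation.T
    return RigidTransform(r_inv, -r_inv @ tf.translation)


def rotation_angle_deg(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic misorientation between two rotations, in degrees [0, 180].

    The rotation angle of ``r1^T r2`` (equivalently
    arccos((trace(r1^T r2) - 1) / 2)), evaluated via atan2 of the
    antisymmetric part so that angles near 0 and 180 keep full
    floating-point resolution.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    for r in (r1, r2):
        if r.shape != (3, 3) or np.abs(r.T @ r - np.eye(3)).max() > 1e-6:
            raise ValueError("inputs must be orthonormal 3x3 rotations")
        if np.linalg.det(r) < 0:
            raise ValueError("inputs must be proper rotations (det +1)")
    d = r1.T @ r2
    c = (np.trace(d) - 1.0) / 2.0
    s = np.linalg.norm(d - d.T, "fro") / (2.0 * np.sqrt(2.0))
    return float(np.degrees(np.arctan2(s, c)))


def residual_rms(tf: RigidTransform, corr: LandmarkCorrespondence) -> float:
    """Root-mean-square landmark misfit of ``tf`` on ``corr``, in mm."""
    d = apply_transform(tf, corr.source) - corr.target
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
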