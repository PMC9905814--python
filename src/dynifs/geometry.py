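"""Minimum distance between posed cortical bone surfaces.

The ischiofemoral space (IFS) at one capture frame is the shortest
Euclidean distance between the lateral cortex of the ischial tuberosity
(pelvis) and the medial cortex of the lesser trochanter (femur), each
posed by its frame transform.  The distance is defined point-to-triangle
over the ROI faces in both directions (vertices of one surface against
triangles of the other), which avoids the upward bias of vertex-to-vertex
sampling on smooth cortical surfaces.

A sphere-pruning step (KD-tree upper bound + triangle bounding-sphere
lower bounds) accelerates the search without changing the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import BoneModel
from .kinematics import FrameTransformSeries, NormalizedCurve, normalize_to_cycle
from .registration import RigidTransform, apply_transform

__all__ = ["IfsCurve", "min_distance", "ifs_series", "closest_point_on_triangles"]


@dataclass
class IfsCurve:
    """Per-frame minimum bone-to-bone distance (mm) with its gait-cycle
    normalization.  ``contact`` flags frames where the posed surfaces
    touch or intersect (distance reported as 0)."""

    distance_mm: np.ndarray
    normalized: NormalizedCurve | None = None
    contact: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        if self.contact is None:
            self.contact = np.zeros(self.distance_mm.shape, dtype=bool)

    @property
    def argmax_percent(self) -> float:
        if self.normalized is None:
            raise ValueError("curve has no normalization")
        return float(self.normalized.percent[int(np.argmax(self.normalized.values))])

    @property
    def argmin_percent(self) -> float:
        if self.normalized is None:
            raise ValueError("curve has no normalization")
        return float(self.normalized.percent[int(np.argmin(self.normalized.values))])


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on triangles[i] to points[i] (paired arrays).

    points: (K, 3); triangles: (K, 3, 3) -> (K, 3) closest points.
    """
    return _closest_paired(np.asarray(points, float), np.asarray(triangles, float))


def min_distance(model_a: BoneModel, roi_a: str, tf_a: RigidTransform,
                 model_b: BoneModel, roi_b: str, tf_b: RigidTransform,
                 ) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum distance between two posed ROI surfaces, with the witness
    point pair realizing it.

    Symmetric in its two surfaces; returns 0 (with coincident witnesses)
    if the surfaces touch or intersect at a sampled pair.
    """
    va, fa = _posed_roi(model_a, roi_a, tf_a)
    vb, fb = _posed_roi(model_b, roi_b, tf_b)

    # upper bound from vertex-vertex nearest neighbours
    tree_b = cKDTree(vb)
    d_ab, _ = tree_b.query(va, k=1)
    upper = float(d_ab.min())

    best = upper
    # witness initialisation from the vertex pair achieving the bound
    ia = int(np.argmin(d_ab))
    _, ib = tree_b.query(va[ia], k=1)
    wa, wb = va[ia].copy(), vb[int(ib)].copy()

    for pts, tris, swap in ((va, vb[fb], False), (vb, va[fa], True)):
        d, p, q = _min_points_triangles(pts, tris, best)
        if p is not None and d <= best:
            best = d
            wa, wb = (q, p) if swap else (p, q)
    return best, wa, wb


def _min_points_triangles(points: np.ndarray, triangles: np.ndarray,
                          upper_bound: float) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    if triangles.shape[0] == 0:
        return upper_bound, None, None
    cent = triangles.mean(axis=1)
    rad = np.linalg.norm(triangles - cent[:, None, :], axis=2).max(axis=1)
    d_cent = np.linalg.norm(points[:, None, :] - cent[None, :, :], axis=2)
    cand = (d_cent - rad[None, :]) <= upper_bound + 1e-9
    pi, tj = np.nonzero(cand)
    if pi.size == 0:
        return upper_bound, None, None
    best = np.inf
    best_p = best_q = None
    for s in range(0, pi.size, 100_000):
        ii = pi[s : s + 100_000]
        jj = tj[s : s + 100_000]
        cp = _closest_paired(points[ii], triangles[jj])
        d = np.linalg.norm(points[ii] - cp, axis=1)
        k = int(np.argmin(d))
        if d[k] < best:
            best = float(d[k])
            best_p = points[ii[k]].copy()
            best_q = cp[k].copy()
    return best, best_p, best_q


def _closest_paired(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on tri[i] to p[i]; Ericson region classification,
    vectorized over paired inputs (K, 3) / (K, 3, 3)."""
    a, b, c = tri[:, 0, :], tri[:, 1, :], tri[:, 2, :]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=1)
    d2 = np.sum(ac * ap, axis=1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=1)
    d4 = np.sum(ac * bp, axis=1)
    cp_ = p - c
    d5 = np.sum(ab * cp_, axis=1)
    d6 = np.sum(ac * cp_, axis=1)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)                       # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)                      # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)                      # vertex C

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(d1 != d3, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v[:, None] * ab)   # edge AB

    vb_ = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(d2 != d6, d2 / (d2 - d6), 0.0)
    assign((vb_ <= 0) & (d2 >= 0) & (d6 <= 0), a + w[:, None] * ac)  # edge AC

    va_ = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    assign((va_ <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w[:, None] * (c - b))  # edge BC

    # interior
    denom = va_ + vb_ + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb_ / denom, 1.0 / 3.0)
        w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    rest = ~done
    out[rest] = (a + v[:, None] * ab + w[:, None] * ac)[rest]
    return out


def _posed_roi(model: BoneModel, roi: str, tf: RigidTransform) -> tuple[np.ndarray, np.ndarray]:
    """Posed vertices (restricted to the ROI, reindexed) and face array."""
    faces = model.roi_faces(roi)
    idx = model.rois[roi]
    used = np.unique(np.concatenate([idx, faces.ravel()])) if faces.size else idx
    remap = -np.ones(model.vertices.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    verts = apply_transform(tf, model.vertices[used])
    faces_r = remap[faces] if faces.size else faces.reshape(0, 3)
    return verts, faces_r


def ifs_series(pelvis: BoneModel, femur: BoneModel,
               pelvis_tfs: FrameTransformSeries, femur_tfs: FrameTransformSeries,
               rois: tuple[str, str] = ("ischial_tuberosity_lateral_cortex",
                                        "lesser_trochanter_medial_cortex"),
               cycle: tuple[int, int] | None = None,
               n_nodes: int = 101) -> IfsCurve:
    """Per-frame IFS between the posed pelvis and femur ROIs.

    Frames invalid in either transform series yield NaN.  When ``cycle``
    (a heel-strike to heel-strike frame span) is given, the series is
    also resampled onto ``n_nodes`` gait-cycle percentages.
    """
    if pelvis_tfs.n_frames != femur_tfs.n_frames:
        raise ValueError("transform series must cover the same frames")
    n = pelvis_tfs.n_frames
    both = pelvis_tfs.valid & femur_tfs.valid
    if not both.any():
        raise ValueError("no overlapping valid frames between the two segments")
    dist = np.full(n, np.nan)
    contact = np.zeros(n, dtype=bool)
    for f in range(n):
        if not both[f]:
            continue
        d, _, _ = min_distance(pelvis, rois[0], pelvis_tfs.transforms[f],
                               femur, rois[1], femur_tfs.transforms[f])
        dist[f] = max(d, 0.0)
        contact[f] = d <= 0.0
    normalized = normalize_to_cycle(dist, cycle, n_nodes) if cycle is not None else None
    return IfsCurve(dist, normalized, contact)
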