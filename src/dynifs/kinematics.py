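"""Marker trajectories -> per-frame bone poses and gait-cycle series.

Each body segment carries a cluster of skin markers whose neutral
(imaging-frame) coordinates are known.  Per capture frame the rigid
transform taking the neutral cluster onto the measured cluster is fitted
by least squares; applying it to the bone landmarks A yields their lab
trajectories B = R A + t.  Gait events come from a vertical
ground-reaction-force threshold (10 N), and cycle-level series are
resampled to 101 nodes (0..100 % of the gait cycle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .io_formats import GrfRecord, MarkerTrajectorySet
from .registration import (
    LandmarkCorrespondence,
    RigidTransform,
    apply_transform,
    estimate_rigid_transform,
    residual_rms,
)

__all__ = [
    "FrameTransformSeries",
    "GaitEvents",
    "NormalizedCurve",
    "fit_frame_transforms",
    "bone_landmark_trajectories",
    "detect_gait_events",
    "normalize_to_cycle",
    "interpolate_gaps",
]

DEFAULT_GRF_THRESHOLD_N = 10.0
DEFAULT_NODES = 101
MAX_GAP_FRAMES = 10
DEBOUNCE_S = 0.05


@dataclass
class FrameTransformSeries:
    """Per-frame rigid transforms for one segment; ``transforms[i]`` is
    None where ``valid[i]`` is False.  ``residual_rms`` is the per-frame
    registration misfit in mm."""

    transforms: list[RigidTransform | None]
    residual_rms: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.residual_rms = np.asarray(self.residual_rms, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.transforms)
        if self.residual_rms.shape != (n,) or self.valid.shape != (n,):
            raise ValueError("series length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.transforms)


@dataclass
class GaitEvents:
    heel_strikes: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self) -> None:
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=np.int64)
        self.toe_offs = np.asarray(self.toe_offs, dtype=np.int64)
        for arr in (self.heel_strikes, self.toe_offs):
            if arr.size > 1 and not (np.diff(arr) > 0).all():
                raise ValueError("event frames must be strictly increasing")

    def cycles(self) -> list[tuple[int, int]]:
        """Complete heel-strike -> next heel-strike spans."""
        hs = self.heel_strikes
        return [(int(hs[i]), int(hs[i + 1])) for i in range(len(hs) - 1)]


@dataclass
class NormalizedCurve:
    """Scalar waveform on equally spaced gait-cycle percentages."""

    values: np.ndarray
    n_nodes: int = DEFAULT_NODES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_nodes,):
            raise ValueError(f"expected {self.n_nodes} nodes, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("curve values must be finite")

    @property
    def percent(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.n_nodes)


def interpolate_gaps(markers: MarkerTrajectorySet,
                     max_gap: int = MAX_GAP_FRAMES) -> MarkerTrajectorySet:
    """Cubic-spline fill of marker gaps up to ``max_gap`` frames long.

    Longer gaps (and gaps touching the record ends) stay invalid.
    """
    pos = markers.positions.copy()
    mask = markers.valid_mask.copy()
    n = markers.n_frames
    for j in range(len(markers.labels)):
        col = mask[:, j]
        if col.all() or col.sum() < 4:
            continue
        invalid = ~col
        # locate runs of invalid frames
        edges = np.flatnonzero(np.diff(np.concatenate(([0], invalid.view(np.int8), [0]))))
        starts, ends = edges[::2], edges[1::2]
        good = np.flatnonzero(col)
        spline = CubicSpline(good, pos[col, j, :], axis=0)
        for s, e in zip(starts, ends):
            if e - s <= max_gap and s > 0 and e < n:
                idx = np.arange(s, e)
                pos[idx, j, :] = spline(idx)
                mask[idx, j] = True
    return MarkerTrajectorySet(list(markers.labels), pos, markers.rate, mask)


def fit_frame_transforms(markers: MarkerTrajectorySet,
                         neutral: dict[str, np.ndarray],
                         fill_gaps: bool = True) -> FrameTransformSeries:
    """Fit one rigid transform per frame from the neutral cluster to the
    measured marker cluster.

    ``neutral`` maps marker labels to neutral (imaging-frame) positions;
    at least three labels must also exist in ``markers``.  Frames with
    fewer than three valid markers are flagged invalid.
    """
    shared = [lb for lb in markers.labels if lb in neutral]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared labels between markers and neutral set, got {shared}"
        )
    if fill_gaps:
        markers = interpolate_gaps(markers)
    pos, mask = markers.positions_of(shared)
    p_all = np.array([neutral[lb] for lb in shared], dtype=float)

    n = markers.n_frames
    transforms: list[RigidTransform | None] = []
    res = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for f in range(n):
        sel = mask[f]
        if sel.sum() < 3:
            transforms.append(None)
            continue
        corr = LandmarkCorrespondence(p_all[sel], pos[f, sel])
        try:
            tf = estimate_rigid_transform(corr)
        except ValueError:
            transforms.append(None)
            continue
        transforms.append(tf)
        res[f] = residual_rms(tf, corr)
        valid[f] = True
    if not valid.any():
        raise ValueError("no frame could be registered (all invalid)")
    return FrameTransformSeries(transforms, res, valid)


def bone_landmark_trajectories(series: FrameTransformSeries,
                               bone_landmarks: np.ndarray) -> np.ndarray:
    """Apply each frame's transform to the bone landmark set A.

    Returns (n_frames, n_landmarks, 3); invalid frames are NaN.
    """
    a = np.atleast_2d(np.asarray(bone_landmarks, dtype=float))
    out = np.full((series.n_frames, a.shape[0], 3), np.nan)
    for f, tf in enumerate(series.transforms):
        if tf is not None:
            out[f] = apply_transform(tf, a)
    return out


def detect_gait_events(grf: GrfRecord,
                       threshold: float = DEFAULT_GRF_THRESHOLD_N) -> GaitEvents:
    """Threshold-crossing gait events on the vertical GRF.

    Heel strike = upward crossing of ``threshold``; toe off = downward
    crossing.  Crossings closer than 50 ms are merged (debounce).
    """
    fz = grf.vertical
    above = fz > threshold
    d = np.diff(above.view(np.int8))
    ups = np.flatnonzero(d == 1) + 1
    downs = np.flatnonzero(d == -1) + 1
    ups = _debounce(ups, grf.rate)
    downs = _debounce(downs, grf.rate)
    if ups.size == 0 and downs.size == 0:
        warnings.warn("no GRF threshold crossings found; no gait events", stacklevel=2)
    return GaitEvents(ups, downs)


def _debounce(frames: np.ndarray, rate: float, min_gap_s: float = DEBOUNCE_S) -> np.ndarray:
    if frames.size == 0:
        return frames
    min_gap = max(1, int(round(min_gap_s * rate)))
    keep = [int(frames[0])]
    for f in frames[1:]:
        if f - keep[-1] >= min_gap:
            keep.append(int(f))
    return np.asarray(keep, dtype=np.int64)


def normalize_to_cycle(series: np.ndarray, cycle: tuple[int, int],
                       q: int = DEFAULT_NODES) -> NormalizedCurve:
    """Resample a per-frame scalar onto ``q`` equally spaced gait-cycle
    percentages by linear time interpolation.

    ``cycle`` is a (heel_strike, next_heel_strike) frame span; its two
    endpoints map to 0 % and 100 %.  NaN samples inside the span are
    bridged linearly from valid neighbours; an all-NaN span is an error.
    """
    s0, s1 = cycle
    if s1 - s0 < 2:
        raise ValueError("cycle span must cover at least 2 frames")
    y = np.asarray(series, dtype=float)[s0 : s1 + 1]
    x = np.arange(len(y), dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError("cycle span has fewer than 2 valid samples")
    xq = np.linspace(0.0, len(y) - 1.0, q)
    vals = np.interp(xq, x[ok], y[ok])
    return NormalizedCurve(vals, q)
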