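"""Readers and writers for every external format the pipeline touches.

Internal units are fixed: millimetres for positions, newtons for forces,
hertz for rates.  Any file-level unit conversion (e.g. a TRC header
declaring metres) happens here and only here.  The lab frame is
right-handed, Z-up, mm; readers never reorient.

Marker TSV house dialect::

    Frame<TAB>Time<TAB><label>_X<TAB><label>_Y<TAB><label>_Z ...

one row per capture frame.  Gaps are empty cells or NaN and become
``valid_mask == False``; no gap filling happens at I/O time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .registration import RigidTransform

__all__ = [
    "MarkerTrajectorySet",
    "GrfRecord",
    "BoneModel",
    "read_markers",
    "write_markers_tsv",
    "read_bone_model",
    "read_grf",
    "read_curve",
    "write_curve",
    "read_transforms",
    "write_transforms",
]


@dataclass
class MarkerTrajectorySet:
    """Labelled marker positions over frames.

    Attributes
    ----------
    labels : list of str
        Marker names, one per column of ``positions``.
    positions : ndarray, shape (n_frames, n_markers, 3)
        Lab-frame coordinates in mm.  Entries where ``valid_mask`` is
        False are NaN, never silent zeros.
    rate : float
        Capture frequency, Hz.
    valid_mask : ndarray of bool, shape (n_frames, n_markers)
    """

    labels: list[str]
    positions: np.ndarray
    rate: float
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_markers, 3)")
        if self.positions.shape[1] != len(self.labels):
            raise ValueError("label count does not match positions")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate marker labels")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.positions).all(axis=2)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.positions.shape[:2]:
            raise ValueError("valid_mask shape mismatch")
        if not np.isfinite(self.positions[self.valid_mask]).all():
            raise ValueError("positions must be finite wherever valid")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def positions_of(self, labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Positions and validity restricted to ``labels``, in that order."""
        try:
            idx = [self.labels.index(lb) for lb in labels]
        except ValueError as exc:
            missing = [lb for lb in labels if lb not in self.labels]
            raise KeyError(f"marker label(s) not in trajectory set: {missing}") from exc
        return self.positions[:, idx, :], self.valid_mask[:, idx]


@dataclass
class GrfRecord:
    """Ground-reaction-force series in N at ``rate`` Hz.  ``force`` is
    (n_frames,) vertical component or (n_frames, 3)."""

    force: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if not np.isfinite(self.force).all():
            raise ValueError("force values must be finite")

    @property
    def vertical(self) -> np.ndarray:
        return self.force if self.force.ndim == 1 else self.force[:, -1]


@dataclass
class BoneModel:
    """Triangle mesh plus named landmarks and cortical regions of interest.

    ``bone_landmarks`` live on/inside the bone (the registration set A);
    ``surface_landmarks`` are the neutral-position skin landmark
    coordinates in the same imaging frame.  ``rois`` map names such as
    ``"ischial_tuberosity_lateral_cortex"`` to vertex-index arrays.
    """

    vertices: np.ndarray
    faces: np.ndarray
    bone_landmarks: dict[str, np.ndarray]
    surface_landmarks: dict[str, np.ndarray]
    rois: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        nv = self.vertices.shape[0]
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= nv):
            raise ValueError("face indices out of range")
        overlap = set(self.bone_landmarks) & set(self.surface_landmarks)
        if overlap:
            raise ValueError(f"landmark name collision between bone and surface sets: {sorted(overlap)}")
        self.bone_landmarks = {k: np.asarray(v, float).reshape(3) for k, v in self.bone_landmarks.items()}
        self.surface_landmarks = {k: np.asarray(v, float).reshape(3) for k, v in self.surface_landmarks.items()}
        clean_rois = {}
        for name, idx in self.rois.items():
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size == 0:
                raise ValueError(f"ROI {name!r} is empty")
            if idx.min() < 0 or idx.max() >= nv:
                raise ValueError(f"ROI {name!r} has vertex index out of range (n_vertices={nv})")
            clean_rois[name] = idx
        self.rois = clean_rois

    def roi_faces(self, name: str) -> np.ndarray:
        """Faces whose three vertices all belong to the named ROI."""
        if name not in self.rois:
            raise KeyError(f"unknown ROI {name!r}; available: {sorted(self.rois)}")
        member = np.zeros(self.vertices.shape[0], dtype=bool)
        member[self.rois[name]] = True
        keep = member[self.faces].all(axis=1)
        return self.faces[keep]

    def landmark_array(self, which: str = "bone") -> tuple[list[str], np.ndarray]:
        lm = self.bone_landmarks if which == "bone" else self.surface_landmarks
        names = sorted(lm)
        return names, np.array([lm[n] for n in names])


# ---------------------------------------------------------------------------
# markers

def read_markers(path: str | Path, dialect: str = "tsv") -> MarkerTrajectorySet:
    """Read marker trajectories from the house TSV dialect or a TRC file.

    TRC ``Units`` headers of ``m`` are converted to mm; positions are
    always mm on return.  Missing samples yield ``valid_mask == False``.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_markers_tsv(path)
    if dialect == "trc":
        return _read_markers_trc(path)
    raise ValueError(f"unknown marker dialect {dialect!r}; expected 'tsv' or 'trc'")


def _read_markers_tsv(path: Path) -> MarkerTrajectorySet:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        raise ValueError("duplicate column names in marker TSV header")
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if cols[:2] != ["Frame", "Time"]:
        raise ValueError("marker TSV must start with 'Frame' and 'Time' columns")
    labels: list[str] = []
    for c in cols[2:]:
        if c.endswith("_X"):
            labels.append(c[:-2])
    for lb in labels:
        for ax in "XYZ":
            if f"{lb}_{ax}" not in df.columns:
                raise ValueError(f"marker {lb!r} is missing its {ax} column")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate marker labels in TSV header")
    time = df["Time"].to_numpy(dtype=float)
    if len(time) > 1 and not (np.diff(time) > 0).all():
        raise ValueError("time column must be strictly increasing")
    rate = 1.0 / float(np.median(np.diff(time))) if len(time) > 1 else 100.0
    pos = np.stack(
        [df[[f"{lb}_X", f"{lb}_Y", f"{lb}_Z"]].to_numpy(dtype=float) for lb in labels],
        axis=1,
    )
    return MarkerTrajectorySet(labels, pos, round(rate, 6))


def write_markers_tsv(markers: MarkerTrajectorySet, path: str | Path) -> None:
    data: dict[str, np.ndarray] = {
        "Frame": np.arange(markers.n_frames),
        "Time": np.arange(markers.n_frames) / markers.rate,
    }
    pos = markers.positions.copy()
    pos[~markers.valid_mask] = np.nan
    for j, lb in enumerate(markers.labels):
        for k, ax in enumerate("XYZ"):
            data[f"{lb}_{ax}"] = pos[:, j, k]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.9f")


def _read_markers_trc(path: Path) -> MarkerTrajectorySet:
    # TRC layout: 3 header rows of metadata, a marker-name row, an X1/Y1/Z1
    # row, then data rows Frame# / Time / x y z per marker.
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise ValueError("truncated TRC file")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    rate = float(meta.get("DataRate", meta.get("CameraRate", "100")))
    units = meta.get("Units", "mm").strip().lower()
    scale = {"mm": 1.0, "m": 1000.0, "cm": 10.0}.get(units)
    if scale is None:
        raise ValueError(f"unsupported TRC units {units!r}")
    name_row = lines[3].split("\t")
    labels = [c.strip() for c in name_row[2:] if c.strip()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate marker labels in TRC header")
    rows = []
    times = []
    for line in lines[5:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        times.append(float(cells[1]))
        vals = [float(c) if c.strip() else np.nan for c in cells[2 : 2 + 3 * len(labels)]]
        vals += [np.nan] * (3 * len(labels) - len(vals))
        rows.append(vals)
    if len(times) > 1 and not (np.diff(times) > 0).all():
        raise ValueError("TRC time column must be strictly increasing")
    pos = np.array(rows, dtype=float).reshape(len(rows), len(labels), 3) * scale
    return MarkerTrajectorySet(labels, pos, rate)


def write_markers_trc(markers: MarkerTrajectorySet, path: str | Path) -> None:
    n, m = markers.n_frames, len(markers.labels)
    hdr = [
        f"PathFileType\t4\t(X/Y/Z)\t{Path(path).name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{markers.rate:g}\t{markers.rate:g}\t{n}\t{m}\tmm\t{markers.rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(markers.labels) + "\t\t",
        "\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(m)),
    ]
    pos = markers.positions.copy()
    pos[~markers.valid_mask] = np.nan
    body = []
    for f in range(n):
        cells = [str(f + 1), f"{f / markers.rate:.9f}"]
        for j in range(m):
            for k in range(3):
                v = pos[f, j, k]
                cells.append("" if np.isnan(v) else f"{v:.9f}")
        body.append("\t".join(cells))
    Path(path).write_text("\n".join(hdr + body) + "\n")


# ---------------------------------------------------------------------------
# bone models

def read_bone_model(
    mesh_path: str | Path,
    landmarks_path: str | Path,
    roi_path: str | Path | None = None,
) -> BoneModel:
    """Load an STL/PLY mesh plus the landmark/ROI JSON files.

    Landmark JSON schema::

        {"bone": {"name": [x, y, z], ...}, "surface": {"name": [x, y, z], ...}}

    ROI JSON schema::

        {"roi_name": [vertex_index, ...], ...}
    """
    mesh = trimesh.load_mesh(str(mesh_path))
    lm = json.loads(Path(landmarks_path).read_text())
    rois = json.loads(Path(roi_path).read_text()) if roi_path is not None else {}
    return BoneModel(
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=np.int64),
        bone_landmarks={k: np.asarray(v, float) for k, v in lm.get("bone", {}).items()},
        surface_landmarks={k: np.asarray(v, float) for k, v in lm.get("surface", {}).items()},
        rois={k: np.asarray(v, dtype=np.int64) for k, v in rois.items()},
    )


def write_bone_model(model: BoneModel, mesh_path: str | Path,
                     landmarks_path: str | Path, roi_path: str | Path | None = None) -> None:
    trimesh.Trimesh(model.vertices, model.faces, process=False).export(str(mesh_path))
    lm = {
        "bone": {k: list(v) for k, v in model.bone_landmarks.items()},
        "surface": {k: list(v) for k, v in model.surface_landmarks.items()},
    }
    Path(landmarks_path).write_text(json.dumps(lm, indent=1))
    if roi_path is not None:
        Path(roi_path).write_text(
            json.dumps({k: [int(i) for i in v] for k, v in model.rois.items()})
        )


# ---------------------------------------------------------------------------
# GRF and curves

def read_grf(path: str | Path) -> GrfRecord:
    """CSV with header; either a ``force_z`` (or single force) column, or
    ``force_x, force_y, force_z``; optional ``rate`` column (Hz)."""
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError("empty GRF file")
    rate = float(df["rate"].iloc[0]) if "rate" in df.columns else 100.0
    comp = [c for c in ("force_x", "force_y", "force_z") if c in df.columns]
    if len(comp) == 3:
        force = df[comp].to_numpy(dtype=float)
    elif "force_z" in df.columns:
        force = df["force_z"].to_numpy(dtype=float)
    else:
        num = [c for c in df.columns if c not in ("rate", "time", "frame")]
        if not num:
            raise ValueError("no force column found")
        force = df[num[0]].to_numpy(dtype=float)
    if not np.isfinite(force).all():
        raise ValueError("non-numeric or missing cell in GRF file")
    return GrfRecord(force, rate)


def write_grf(grf: GrfRecord, path: str | Path) -> None:
    f = grf.force
    if f.ndim == 1:
        df = pd.DataFrame({"force_z": f})
    else:
        df = pd.DataFrame(f, columns=["force_x", "force_y", "force_z"])
    df.insert(0, "rate", grf.rate)
    df.to_csv(path, index=False, float_format="%.9f")


def write_curve(percent: np.ndarray, values: np.ndarray, path: str | Path,
                value_name: str = "value_mm") -> None:
    """Write a normalized curve as ``percent,<value_name>`` CSV pairs."""
    pd.DataFrame({"percent": percent, value_name: values}).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_curve(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("curve CSV needs percent and value columns")
    return df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)


def read_curve_matrix(path: str | Path) -> np.ndarray:
    """Read a subjects x nodes curve matrix CSV (no index column)."""
    arr = pd.read_csv(path, header=None).to_numpy(dtype=float)
    if arr.ndim != 2:
        raise ValueError("curve matrix must be 2-D")
    return arr


def write_curve_matrix(curves: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(curves, dtype=float)).to_csv(
        path, index=False, header=False, float_format="%.12g"
    )


# ---------------------------------------------------------------------------
# transforms

def write_transforms(transforms: list[RigidTransform | None], path: str | Path) -> None:
    """Serialize per-frame transforms: frame, 9 row-major rotation entries,
    3 translation entries (mm).  Invalid frames are written as NaN rows."""
    rows = []
    for i, tf in enumerate(transforms):
        if tf is None:
            rows.append([i] + [np.nan] * 12)
        else:
            rows.append([i] + list(tf.rotation.ravel()) + list(tf.translation))
    cols = ["frame"] + [f"r{i}{j}" for i in range(3) for j in range(3)] + ["tx", "ty", "tz"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.12g")


def read_transforms(path: str | Path) -> list[RigidTransform | None]:
    df = pd.read_csv(path)
    out: list[RigidTransform | None] = []
    for _, row in df.iterrows():
        vals = row.to_numpy(dtype=float)[1:]
        if np.isnan(vals).any():
            out.append(None)
        else:
            out.append(RigidTransform(vals[:9].reshape(3, 3), vals[9:12]))
    return out
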