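"""Synthetic validation phantom and gait-like scene generators.

The physical validation object is a sphere ("bone") carrying 5 groups of
paired landmarks: a bone landmark b on the sphere surface and a skin
landmark s mounted on a cylinder of group-specific height above b, so
the s-to-b offsets differ between groups like soft-tissue thickness
does.  The rig imposes two known motions: a constant-speed 30 cm slide
along an oblique (not ground-parallel) track, and a 90 degree rotation
on a pan-tilt mount.  The in-silico replica reproduces both with exact
per-frame ground truth, optionally corrupting the skin markers with
isotropic Gaussian noise, so the whole registration pipeline can be
validated against a known answer.

A schematic two-body gait scene (pelvis block with an ischial
prominence, femur shaft with a lesser-trochanter prominence) drives a
mid-stance IFS maximum near 30 % and an initial-swing minimum near 65 %
of the cycle, plus a curve-level cohort generator for power and
false-positive-rate studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .io_formats import BoneModel, GrfRecord, MarkerTrajectorySet
from .registration import RigidTransform

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "build_phantom",
    "simulate_slide",
    "simulate_rotation",
    "simulate_gait_scene",
    "simulate_cohort_curves",
    "add_sta_perturbation",
]

DEFAULT_RADIUS_MM = 50.0
DEFAULT_OFFSETS_MM = (5.0, 8.0, 11.0, 14.0, 17.0)
SLIDE_DISTANCE_MM = 300.0
SLIDE_FRAMES = 990
ROTATION_DEG = 90.0
ROTATION_FRAMES = 1435
DEFAULT_RATE_HZ = 100.0


@dataclass
class PhantomSpec:
    """Sphere-phantom geometry and commanded motion."""

    radius_mm: float = DEFAULT_RADIUS_MM
    offsets_mm: tuple[float, ...] = DEFAULT_OFFSETS_MM
    slide_distance_mm: float = SLIDE_DISTANCE_MM
    slide_axis: tuple[float, float, float] = (2.0, 1.0, 1.0)  # oblique track
    rotation_deg: float = ROTATION_DEG
    rotation_axis: tuple[float, float, float] = (0.0, 1.0, 1.0)
    frames: int | None = None
    rate_hz: float = DEFAULT_RATE_HZ
    noise_sd_mm: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.offsets_mm)) != len(self.offsets_mm):
            raise ValueError("cylinder offsets must be distinct between groups")
        if any(o <= 0 for o in self.offsets_mm):
            raise ValueError("cylinder offsets must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")
        if self.frames is not None and self.frames < 2:
            raise ValueError("need at least 2 frames")
        if np.linalg.norm(self.slide_axis) == 0 or np.linalg.norm(self.rotation_axis) == 0:
            raise ValueError("motion axis must be non-zero")


@dataclass
class PhantomTruth:
    """Ground truth for one simulated phantom run."""

    transforms: list[RigidTransform]
    bone_trajectories: np.ndarray      # (frames, n_landmarks, 3)
    surface_trajectories: np.ndarray   # pre-noise (frames, n_landmarks, 3)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.transforms)
        if self.bone_trajectories.shape[0] != n or self.surface_trajectories.shape[0] != n:
            raise ValueError("trajectory length mismatch with transform count")


def build_phantom(spec: PhantomSpec) -> BoneModel:
    """Triangulated sphere with 5 (surface, bone) landmark pairs.

    Bone landmarks sit on the sphere; each surface landmark is offset
    outward along the local normal by its group's cylinder height.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    mesh = trimesh.creation.icosphere(subdivisions=3, radius=spec.radius_mm)
    # 5 directions spread over both sides of the sphere
    n_groups = len(spec.offsets_mm)
    dirs = []
    base = rng.normal(size=3)
    base /= np.linalg.norm(base)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i in range(n_groups):
        z = 1.0 - 2.0 * (i + 0.5) / n_groups
        r = np.sqrt(max(0.0, 1.0 - z * z))
        th = golden * i
        dirs.append(np.array([r * np.cos(th), r * np.sin(th), z]))
    bone = {}
    surface = {}
    for i, (d, h) in enumerate(zip(dirs, spec.offsets_mm), start=1):
        b = spec.radius_mm * d
        bone[f"b{i}"] = b
        surface[f"s{i}"] = b + h * d
    return BoneModel(
        vertices=np.asarray(mesh.vertices, float),
        faces=np.asarray(mesh.faces, np.int64),
        bone_landmarks=bone,
        surface_landmarks=surface,
        rois={"sphere_surface": np.arange(mesh.vertices.shape[0])},
    )


def _simulate(model: BoneModel, spec: PhantomSpec,
              transforms: list[RigidTransform]) -> tuple[MarkerTrajectorySet, PhantomTruth]:
    rng = np.random.default_rng(spec.seed)
    s_names, s_pts = model.landmark_array("surface")
    b_names, b_pts = model.landmark_array("bone")
    n = len(transforms)
    surf = np.stack([tf.rotation @ s_pts.T for tf in transforms]).transpose(0, 2, 1) \
        + np.stack([tf.translation for tf in transforms])[:, None, :]
    bone = np.stack([tf.rotation @ b_pts.T for tf in transforms]).transpose(0, 2, 1) \
        + np.stack([tf.translation for tf in transforms])[:, None, :]
    measured = surf.copy()
    if spec.noise_sd_mm > 0:
        measured = measured + rng.normal(0.0, spec.noise_sd_mm, size=measured.shape)
    markers = MarkerTrajectorySet(s_names, measured, spec.rate_hz)
    truth = PhantomTruth(transforms, bone, surf, labels=b_names)
    return markers, truth


def simulate_slide(spec: PhantomSpec | None = None,
                   model: BoneModel | None = None,
                   ) -> tuple[MarkerTrajectorySet, PhantomTruth, BoneModel]:
    """Constant-speed slide of the whole assembly along the oblique
    track axis by the commanded distance (default 300 mm over 990
    frames).  Ground-truth rotation is the identity every frame."""
    spec = spec or PhantomSpec()
    model = model or build_phantom(spec)
    frames = spec.frames or SLIDE_FRAMES
    axis = np.asarray(spec.slide_axis, float)
    axis /= np.linalg.norm(axis)
    s = np.linspace(0.0, spec.slide_distance_mm, frames)
    tfs = [RigidTransform(np.eye(3), si * axis) for si in s]
    markers, truth = _simulate(model, spec, tfs)
    return markers, truth, model


def simulate_rotation(spec: PhantomSpec | None = None,
                      model: BoneModel | None = None,
                      mount_point: np.ndarray | None = None,
                      ) -> tuple[MarkerTrajectorySet, PhantomTruth, BoneModel]:
    """Constant-rate rotation about a fixed axis through the mount point
    by the commanded angle (default 90 degrees over 1435 frames)."""
    spec = spec or PhantomSpec()
    model = model or build_phantom(spec)
    frames = spec.frames or ROTATION_FRAMES
    axis = np.asarray(spec.rotation_axis, float)
    axis /= np.linalg.norm(axis)
    mount = np.zeros(3) if mount_point is None else np.asarray(mount_point, float)
    angles = np.deg2rad(np.linspace(0.0, spec.rotation_deg, frames))
    tfs = []
    for th in angles:
        r = _axis_angle(axis, th)
        tfs.append(RigidTransform(r, mount - r @ mount))
    markers, truth = _simulate(model, spec, tfs)
    return markers, truth, model


def _axis_angle(axis: np.ndarray, theta: float) -> np.ndarray:
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


# ---------------------------------------------------------------------------
# gait scene

def _block(center: np.ndarray, size: np.ndarray) -> trimesh.Trimesh:
    m = trimesh.creation.box(extents=size)
    m.apply_translation(center)
    return m


def _concat(m1: trimesh.Trimesh, m2: trimesh.Trimesh) -> tuple[np.ndarray, np.ndarray]:
    """Stack two meshes without vertex merging, preserving index layout."""
    v = np.vstack([np.asarray(m1.vertices, float), np.asarray(m2.vertices, float)])
    f = np.vstack([np.asarray(m1.faces, np.int64),
                   np.asarray(m2.faces, np.int64) + m1.vertices.shape[0]])
    return v, f


def _gait_pose_profile(phase: np.ndarray, effect_mm: float,
                       subject_shift: np.ndarray) -> np.ndarray:
    """Gap waveform (mm) between the two prominences over cycle phase
    in [0, 1): peak near 0.30, trough near 0.65 of the cycle."""
    base = 30.0
    wave = (6.0 * np.cos(2.0 * np.pi * (phase - 0.30))
            + 3.0 * np.cos(4.0 * np.pi * (phase - 0.30)))
    window = np.exp(-0.5 * ((phase - 0.55) / 0.18) ** 2)
    return base + wave - effect_mm * window + subject_shift


def simulate_gait_scene(cycle_duration_s: float = 1.0,
                        rate_hz: float = DEFAULT_RATE_HZ,
                        cohort_effect_mm: float = 0.0,
                        n_subjects: tuple[int, int] = (2, 2),
                        noise_sd_mm: float = 0.0,
                        subject_sd_mm: float = 1.0,
                        seed: int | None = None) -> dict:
    """Two simplified rigid bodies under gait-like relative motion.

    The pelvis block (with an ischial prominence) stays fixed; the femur
    shaft (with a lesser-trochanter prominence) translates along the
    inter-prominence axis following a smooth periodic profile whose IFS
    peaks near 30 % (mid-stance) and dips near 65 % (initial swing) of
    the cycle.  The second ("affected") cohort has its IFS reduced by
    ``cohort_effect_mm`` over a mid-cycle Gaussian window.  Returns a
    dict with the two BoneModels, per-subject marker sets and truth
    transforms, a GRF record crossing 10 N at the cycle boundaries, and
    the truth IFS values per frame.
    """
    if min(n_subjects) < 2:
        raise ValueError("need at least 2 subjects per cohort")
    rng = np.random.default_rng(seed)
    frames = int(round(cycle_duration_s * rate_hz)) + 1

    # pelvis: block 60x60x40 at origin, prominence (small box) toward +x;
    # prominence lateral face at x = 40
    pelvis_mesh = _block(np.zeros(3), np.array([60.0, 60.0, 40.0]))
    prom_p = _block(np.array([35.0, 0.0, 0.0]), np.array([10.0, 20.0, 20.0]))
    pv, pf = _concat(pelvis_mesh, prom_p)
    n_pel = pelvis_mesh.vertices.shape[0]
    pelvis = BoneModel(
        vertices=pv,
        faces=pf,
        bone_landmarks={"ischial_tuberosity": np.array([40.0, 0.0, 0.0])},
        surface_landmarks={
            "asis": np.array([-20.0, 40.0, 30.0]),
            "iliac_crest": np.array([0.0, 45.0, 35.0]),
            "psis": np.array([20.0, 40.0, -30.0]),
        },
        rois={"ischial_tuberosity_lateral_cortex":
              np.arange(n_pel, pv.shape[0])},
    )

    # femur: shaft block + medial prominence facing the pelvis; prominence
    # medial face at x = 85, so the neutral face-to-face gap is 45 mm
    shaft = _block(np.array([110.0, 0.0, 0.0]), np.array([30.0, 30.0, 120.0]))
    prom_f = _block(np.array([90.0, 0.0, 0.0]), np.array([10.0, 20.0, 20.0]))
    fv, ff = _concat(shaft, prom_f)
    n_shaft = shaft.vertices.shape[0]
    femur = BoneModel(
        vertices=fv,
        faces=ff,
        bone_landmarks={"lesser_trochanter": np.array([85.0, 0.0, 0.0])},
        surface_landmarks={
            "greater_trochanter": np.array([130.0, 20.0, 40.0]),
            "thigh_distal": np.array([125.0, 10.0, -60.0]),
            "thigh_anterior": np.array([120.0, 35.0, 0.0]),
        },
        rois={"lesser_trochanter_medial_cortex":
              np.arange(n_shaft, fv.shape[0])},
    )

    phase = np.arange(frames) / (frames - 1)
    neutral_gap = 45.0  # pelvis prominence face x = 40, femur prominence face x = 85

    subjects = []
    for cohort, (label, n_sub) in enumerate(zip(("healthy", "affected"), n_subjects)):
        eff = cohort_effect_mm if label == "affected" else 0.0
        for si in range(n_sub):
            shift = rng.normal(0.0, subject_sd_mm)
            gap = _gait_pose_profile(phase, eff, shift)
            if (gap <= 0).any():
                raise ValueError("cohort effect too large: IFS would go negative")
            dx = gap - neutral_gap
            femur_tfs = [RigidTransform(np.eye(3), np.array([d, 0.0, 0.0]))
                         for d in dx]
            pelvis_tfs = [RigidTransform.identity() for _ in range(frames)]
            markers = _scene_markers(pelvis, femur, pelvis_tfs, femur_tfs,
                                     rate_hz, noise_sd_mm, rng)
            subjects.append({
                "cohort": label,
                "markers": markers,
                "pelvis_tfs": pelvis_tfs,
                "femur_tfs": femur_tfs,
                "truth_ifs": gap,
            })

    # GRF: stance plateau over the first 60 % of each of two cycles
    t2 = np.concatenate([phase, 1.0 + phase[1:]])
    fz = 600.0 * ((t2 % 1.0) < 0.6) * np.sin(np.pi * np.clip((t2 % 1.0) / 0.6, 0, 1)) ** 0.5
    grf = GrfRecord(np.maximum(fz, 0.0), rate_hz)

    return {
        "pelvis": pelvis,
        "femur": femur,
        "subjects": subjects,
        "grf": grf,
        "frames": frames,
        "rois": ("ischial_tuberosity_lateral_cortex", "lesser_trochanter_medial_cortex"),
    }


def _scene_markers(pelvis: BoneModel, femur: BoneModel,
                   pelvis_tfs: list[RigidTransform], femur_tfs: list[RigidTransform],
                   rate_hz: float, noise_sd_mm: float,
                   rng: np.random.Generator) -> MarkerTrajectorySet:
    labels = []
    cols = []
    for model, tfs in ((pelvis, pelvis_tfs), (femur, femur_tfs)):
        names, pts = model.landmark_array("surface")
        labels += names
        traj = np.stack([tf.rotation @ pts.T for tf in tfs]).transpose(0, 2, 1) \
            + np.stack([tf.translation for tf in tfs])[:, None, :]
        cols.append(traj)
    pos = np.concatenate(cols, axis=1)
    if noise_sd_mm > 0:
        pos = pos + rng.normal(0.0, noise_sd_mm, size=pos.shape)
    return MarkerTrajectorySet(labels, pos, rate_hz)


# ---------------------------------------------------------------------------
# curve-level cohort generator (for power / false-positive-rate studies)

def simulate_cohort_curves(n_a: int = 18, n_b: int = 12, n_nodes: int = 101,
                           effect_mm: float = 0.0,
                           effect_window: tuple[float, float] = (40.0, 80.0),
                           noise_sd_mm: float = 2.0, fwhm_nodes: float = 15.0,
                           seed: int | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Smooth Gaussian IFS-like curves for two cohorts.

    Each curve is a shared periodic template plus smooth Gaussian noise
    (pointwise SD ``noise_sd_mm``, smoothness ``fwhm_nodes``).  Cohort B
    is lowered by ``effect_mm`` over ``effect_window`` (percent of
    cycle).  Returns (curves_a, curves_b).
    """
    rng = np.random.default_rng(seed)
    pct = np.linspace(0.0, 100.0, n_nodes)
    template = 30.0 + 8.0 * np.cos(2.0 * np.pi * (pct / 100.0 - 0.30))
    lo, hi = effect_window
    window = ((pct >= lo) & (pct <= hi)).astype(float)
    a = template + _smooth_noise(rng, n_a, n_nodes, fwhm_nodes) * noise_sd_mm
    b = (template - effect_mm * window
         + _smooth_noise(rng, n_b, n_nodes, fwhm_nodes) * noise_sd_mm)
    return a, b


def _smooth_noise(rng: np.random.Generator, n: int, q: int, fwhm: float) -> np.ndarray:
    """Unit-variance Gaussian random curves with given FWHM (nodes),
    via Gaussian-kernel smoothing of white noise on a padded grid."""
    sigma = fwhm / np.sqrt(8.0 * np.log(2.0))
    pad = int(np.ceil(4 * sigma))
    w = rng.normal(size=(n, q + 2 * pad))
    x = np.arange(-pad, pad + 1)
    kern = np.exp(-0.5 * (x / sigma) ** 2)
    kern /= np.sqrt((kern**2).sum())  # unit output variance
    out = np.empty((n, q))
    for i in range(n):
        out[i] = np.convolve(w[i], kern, mode="valid")[:q]
    return out


# ---------------------------------------------------------------------------
# soft-tissue-artifact perturbation

def add_sta_perturbation(markers: MarkerTrajectorySet, amplitude_mm: float,
                         frequency_hz: float = 1.0, seed: int | None = None
                         ) -> MarkerTrajectorySet:
    """Smooth sinusoidal per-marker displacement breaking the rigid-cluster
    assumption, to probe soft-tissue-artifact sensitivity.

    Each marker/axis gets ``amplitude_mm * sin(2 pi f t + phase)`` with a
    seeded random phase; amplitude 0 returns the input unchanged.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude_mm == 0:
        return markers
    rng = np.random.default_rng(seed)
    t = np.arange(markers.n_frames) / markers.rate
    phases = rng.uniform(0, 2 * np.pi, size=(len(markers.labels), 3))
    pert = amplitude_mm * np.sin(
        2 * np.pi * frequency_hz * t[:, None, None] + phases[None, :, :])
    return MarkerTrajectorySet(list(markers.labels), markers.positions + pert,
                               markers.rate, markers.valid_mask.copy())
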