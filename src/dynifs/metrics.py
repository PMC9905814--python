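"""Validation arithmetic: RMSE, between-day CMC, and linear-fit validity.

These quantify how well the registration pipeline reproduces reference
(gold-standard) bone-landmark trajectories: RMSE of position (mm) and of
cluster orientation (degrees, geodesic); the coefficient of multiple
correlation (CMC) for between-session waveform reliability; and the
linear fit method (LFM: slope a1, intercept a0, R^2) for validity
against the reference system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registration import rotation_angle_deg

__all__ = [
    "ValidationReport",
    "GroupSummary",
    "rmse_distance",
    "rmse_angle",
    "cmc",
    "lfm",
    "summarize_groups",
]


def rmse_distance(calculated: np.ndarray, reference: np.ndarray) -> float:
    """Root-mean-square Euclidean error between corresponding landmark
    trajectories, in mm.

    Inputs are (..., 3) arrays of identical shape; the mean runs over all
    leading axes (frames, landmarks).
    """
    calc = np.asarray(calculated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if calc.shape != ref.shape:
        raise ValueError(f"shape mismatch: {calc.shape} vs {ref.shape}")
    d2 = np.sum((calc - ref) ** 2, axis=-1)
    return float(np.sqrt(np.mean(d2)))


def rmse_angle(estimated: list[np.ndarray], reference: list[np.ndarray]) -> float:
    """RMS geodesic misorientation between two rotation series, degrees."""
    if len(estimated) != len(reference):
        raise ValueError("rotation series length mismatch")
    ang = np.array([rotation_angle_deg(r1, r2) for r1, r2 in zip(estimated, reference)])
    return float(np.sqrt(np.mean(ang**2)))


def cmc(waveforms: np.ndarray) -> tuple[float, bool]:
    """Coefficient of multiple correlation of G repeated waveforms.

    ``waveforms`` is (G, F): G repetitions (e.g. measurement days) of an
    F-frame waveform.  Returns ``(value, degenerate)``:

        CMC = sqrt(1 - [ sum (Y_gf - Ybar_f)^2 / (F (G-1)) ]
                       / [ sum (Y_gf - Ybar)^2 / (F G - 1) ])

    with Ybar_f the frame-wise mean and Ybar the grand mean.  When the
    within/between variance ratio exceeds 1 (waveforms less similar than
    flat noise, e.g. parallel constant lines) the CMC is undefined under
    the square root; the degenerate flag is set and 0 returned.
    """
    y = np.asarray(waveforms, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need at least 2 repetitions of at least 2 frames")
    g, f = y.shape
    frame_mean = y.mean(axis=0)
    grand_mean = y.mean()
    num = np.sum((y - frame_mean) ** 2) / (f * (g - 1))
    den = np.sum((y - grand_mean) ** 2) / (f * g - 1)
    if den == 0:
        return 0.0, True
    ratio = num / den
    if ratio > 1:
        return 0.0, True
    return float(np.sqrt(1.0 - ratio)), False


def lfm(reference: np.ndarray, test: np.ndarray) -> tuple[float, float, float]:
    """Linear fit method: OLS of test on reference.

    Returns (a1 slope, a0 intercept, R^2) of ``test = a1*reference + a0``;
    R^2 is the squared Pearson correlation.
    """
    x = np.asarray(reference, dtype=float).ravel()
    y = np.asarray(test, dtype=float).ravel()
    if x.shape != y.shape or x.size < 3:
        raise ValueError("waveforms must share a length of at least 3")
    sx = x.std()
    if sx == 0:
        raise ValueError("reference waveform is constant; LFM undefined")
    a1, a0 = np.polyfit(x, y, 1)
    sy = y.std()
    r2 = 0.0 if sy == 0 else float(np.corrcoef(x, y)[0, 1] ** 2)
    return float(a1), float(a0), r2


@dataclass
class GroupSummary:
    name: str
    n: int
    mean: float
    sd: float
    ci_lower: float
    ci_upper: float
    rmse: float


@dataclass
class ValidationReport:
    """Per-group error summaries plus a pooled 'Total' row (all frames
    concatenated, not averaged group statistics)."""

    groups: list[GroupSummary]
    total: GroupSummary
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        rows = [vars(g) for g in self.groups] + [vars(self.total)]
        return {"rows": rows, **self.extra}


def summarize_groups(errors: dict[str, np.ndarray], z: float = 1.96) -> ValidationReport:
    """Mean, SD, normal-theory 95 % CI and RMSE per group of scalar errors,
    plus a pooled total over all frames concatenated."""
    if not errors:
        raise ValueError("no groups provided")
    groups = []
    for name, e in errors.items():
        e = np.asarray(e, dtype=float).ravel()
        if e.size == 0:
            raise ValueError(f"group {name!r} is empty")
        groups.append(_summary(name, e, z))
    pooled = np.concatenate([np.asarray(e, float).ravel() for e in errors.values()])
    return ValidationReport(groups, _summary("Total", pooled, z))


def _summary(name: str, e: np.ndarray, z: float) -> GroupSummary:
    n = e.size
    mean = float(e.mean())
    sd = float(e.std(ddof=1)) if n > 1 else 0.0
    half = z * sd / np.sqrt(n)
    return GroupSummary(name, n, mean, sd, mean - half, mean + half,
                        float(np.sqrt(np.mean(e**2))))
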