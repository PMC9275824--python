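"""Pupillometry from landmark points: Taubin circle fits and frame QC.

Each video frame carries a set of landmark points on the pupil rim with
per-point confidence.  A frame's "core" points are those with likelihood
> 0.7; a circle is fitted with the Taubin SVD algebraic method whenever a
frame has more than 3 core points.  A session passes quality control when
the mean likelihood across detected points exceeds 0.95 and more than 97%
of frames are valid.  Pupil diameter is twice the fitted radius, with gaps
of up to 0.5 s linearly interpolated; blinks are flagged where the mean
landmark likelihood drops more than 0.5 below its 1 s rolling median
(an operational criterion, exposed as a parameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PupilFrame",
    "taubin_fit",
    "frame_validity",
    "diameter_trace",
    "detect_blinks",
]

CORE_LIKELIHOOD = 0.7
MIN_CORE_POINTS = 4  # "more than 3"
QC_MEAN_LIKELIHOOD = 0.95
QC_VALID_FRACTION = 0.97


@dataclass
class PupilFrame:
    points: np.ndarray  # (n, 3): x, y, likelihood
    circle: tuple[float, float, float] | None = None  # (cx, cy, r)
    valid: bool = False


def taubin_fit(points: np.ndarray) -> tuple[float, float, float]:
    """Taubin SVD-based algebraic circle fit.

    Exact on noiseless circles; raises on collinear input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4 or pts.shape[1] < 2:
        raise ValueError("need >= 4 (x, y) points")
    x = pts[:, 0] - pts[:, 0].mean()
    y = pts[:, 1] - pts[:, 1].mean()
    z = x**2 + y**2
    zm = z.mean()
    if zm <= 0:
        raise ValueError("degenerate points")
    z0 = (z - zm) / (2.0 * np.sqrt(zm))
    design = np.column_stack([z0, x, y]) / np.sqrt(len(x))
    _, svals, vt = np.linalg.svd(design, full_matrices=False)
    coef = vt[-1]
    a = coef[0] / (2.0 * np.sqrt(zm))
    b, c = coef[1], coef[2]
    d = -zm * a
    if abs(a) < 1e-12 * max(abs(b), abs(c), 1.0):
        raise ValueError("collinear points: circle fit undefined")
    cx = -b / (2.0 * a)
    cy = -c / (2.0 * a)
    r2 = (b**2 + c**2) / (4.0 * a**2) - d / a
    if r2 <= 0:
        raise ValueError("degenerate fit: nonpositive radius")
    return (
        float(cx + pts[:, 0].mean()),
        float(cy + pts[:, 1].mean()),
        float(np.sqrt(r2)),
    )


def frame_validity(
    frames: list[np.ndarray] | list[PupilFrame],
) -> tuple[list[PupilFrame], bool]:
    """Per-frame validity and circle fits plus the session QC verdict.

    A frame is valid iff it has more than 3 points with likelihood > 0.7
    and the Taubin fit succeeds; the session passes iff the mean likelihood
    over detected points is > 0.95 and the valid-frame fraction > 0.97.
    """
    out: list[PupilFrame] = []
    all_likes: list[float] = []
    for fr in frames:
        pts = fr.points if isinstance(fr, PupilFrame) else np.asarray(fr, float)
        likes = pts[:, 2] if pts.size else np.array([])
        all_likes.extend(likes.tolist())
        core = pts[likes > CORE_LIKELIHOOD] if pts.size else pts
        circle, valid = None, False
        if len(core) >= MIN_CORE_POINTS:
            try:
                circle = taubin_fit(core[:, :2])
                valid = True
            except ValueError:
                pass
        out.append(PupilFrame(points=pts, circle=circle, valid=valid))
    valid_frac = np.mean([f.valid for f in out]) if out else 0.0
    mean_like = np.mean(all_likes) if all_likes else 0.0
    passes = bool(mean_like > QC_MEAN_LIKELIHOOD and valid_frac > QC_VALID_FRACTION)
    return out, passes


def diameter_trace(
    frames: list[PupilFrame], fps: float, max_gap_s: float = 0.5
) -> np.ndarray:
    """Pupil diameter (2r) per frame; short invalid gaps interpolated."""
    diam = np.array(
        [2.0 * f.circle[2] if f.valid and f.circle else np.nan for f in frames]
    )
    bad = np.isnan(diam)
    if not bad.any() or bad.all():
        return diam
    idx = np.arange(len(diam))
    filled = np.interp(idx, idx[~bad], diam[~bad])
    # re-blank gaps longer than max_gap_s
    max_gap = int(round(max_gap_s * fps))
    j = 0
    while j < len(diam):
        if bad[j]:
            k = j
            while k + 1 < len(diam) and bad[k + 1]:
                k += 1
            if (k - j + 1) > max_gap or j == 0 or k == len(diam) - 1:
                filled[j : k + 1] = np.nan
            j = k + 1
        else:
            j += 1
    return filled


def detect_blinks(
    frames: list[PupilFrame], fps: float, drop: float = 0.5, window_s: float = 1.0
) -> np.ndarray:
    """Frame indices of abrupt likelihood drops (candidate blinks).

    Operationalised as frames whose mean landmark likelihood falls more
    than ``drop`` below a 1 s rolling median of that likelihood.
    """
    mean_like = np.array(
        [f.points[:, 2].mean() if len(f.points) else 0.0 for f in frames]
    )
    win = max(int(round(window_s * fps)) | 1, 3)
    med = (
        pd.Series(mean_like)
        .rolling(win, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return np.nonzero(mean_like < med - drop)[0]
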