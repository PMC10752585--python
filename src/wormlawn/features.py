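"""Frame-level locomotion features and contiguous 10-s binned features.

Frame features are computed from the oriented 49-point spline: speeds use
centered finite differences (mm/s), angular speeds the arc-cosine of the
angle between successive displacement vectors (deg/s), head motion relative
to the midbody is expressed in polar coordinates (r, Phi) around the midbody
centroid, and quirkiness Q = sqrt(1 - a^2/A^2) measures bounding-box
elongation. Missing (invisible) frames propagate NaN; a feature that needs a
neighbor frame is missing whenever that neighbor is.

Binned features are non-overlapping 10-s aggregates anchored at the first
frame; the trailing partial bin is dropped. These bins are the observation
space of the roam/dwell classifiers and of the AR-HMM.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ._geom import min_area_bounding_box, wrap_angle_deg
from .core import MIDBODY_SLICE, Trajectory

__all__ = [
    "PAUSE_THRESHOLD_MM_S",
    "ARHMM_FEATURES",
    "body_part_centroids",
    "path_speed",
    "signed_midbody_speed",
    "angular_speed",
    "head_motion_relative_to_midbody",
    "quirkiness",
    "motion_state",
    "compute_frame_features",
    "bin_features",
]

#: |midbody speed| below this is a pause (mm/s)
PAUSE_THRESHOLD_MM_S = 0.02

#: canonical AR-HMM observation vector (D = 5), in order
ARHMM_FEATURES = (
    "frac_forward",
    "midbody_forward_speed",
    "midbody_angular_speed",
    "head_angular_velocity_rel",
    "head_radial_velocity_rel",
)


def body_part_centroids(spline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Head (mean of points 1-8) and midbody (mean of points 17-33) centroids.

    Accepts one spline (49, 2) or a stack (T, 49, 2); NaN splines give NaN.
    """
    spline = np.asarray(spline, dtype=float)
    head = spline[..., 0:8, :].mean(axis=-2)
    midbody = spline[..., MIDBODY_SLICE, :].mean(axis=-2)
    return head, midbody


def path_speed(positions: np.ndarray, fps: float) -> np.ndarray:
    """Centered-difference speed |x(t+1) - x(t-1)| * fps / 2 in mm/s.

    Endpoints and frames with a missing neighbor are NaN.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    pos = np.asarray(positions, dtype=float)
    if len(pos) < 2:
        raise ValueError("need at least 2 frames")
    out = np.full(len(pos), np.nan)
    d = pos[2:] - pos[:-2]
    out[1:-1] = np.linalg.norm(d, axis=-1) * fps / 2.0
    return out


def _velocity(positions: np.ndarray, fps: float) -> np.ndarray:
    """Centered-difference velocity vector per frame (mm/s); NaN at edges."""
    pos = np.asarray(positions, dtype=float)
    out = np.full_like(pos, np.nan)
    out[1:-1] = (pos[2:] - pos[:-2]) * fps / 2.0
    return out


def signed_midbody_speed(midbody: np.ndarray, body_axis: np.ndarray,
                         fps: float) -> np.ndarray:
    """Midbody speed signed by the direction of travel along the body.

    Magnitude is the centered-difference path speed; the sign is that of the
    projection of the midbody velocity onto the local tail-to-head axis
    (+ forward, - backward). A zero projection keeps a + sign.
    """
    speed = path_speed(midbody, fps)
    vel = _velocity(midbody, fps)
    axis = np.asarray(body_axis, dtype=float)
    proj = np.einsum("ij,ij->i", vel, axis)
    sign = np.where(proj < 0, -1.0, 1.0)
    return sign * speed


def angular_speed(positions: np.ndarray, fps: float) -> np.ndarray:
    """Turning rate in deg/s from three consecutive positions.

    At frame t, the angle between v01 = x(t) - x(t-1) and v12 = x(t+1) - x(t)
    is arccos(<v01, v12> / (|v01||v12|)); multiplied by fps. Missing when a
    neighbor is missing or either displacement is zero.
    """
    pos = np.asarray(positions, dtype=float)
    out = np.full(len(pos), np.nan)
    v01 = pos[1:-1] - pos[:-2]
    v12 = pos[2:] - pos[1:-1]
    n1 = np.linalg.norm(v01, axis=-1)
    n2 = np.linalg.norm(v12, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", v01, v12) / (n1 * n2)
    cosang = np.clip(cosang, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang)) * fps
    ang[(n1 == 0) | (n2 == 0)] = np.nan
    out[1:-1] = ang
    return out


def head_motion_relative_to_midbody(head: np.ndarray, midbody: np.ndarray,
                                    fps: float) -> tuple[np.ndarray, np.ndarray]:
    """(dr/dt in mm/s, dPhi/dt in deg/s) of the head around the midbody.

    The relative vector head - midbody is expressed in polar coordinates
    (Phi, r); both derivatives are centered differences, with Phi steps
    wrapped into (-180, 180]. The angular component is missing where r = 0.
    """
    rel = np.asarray(head, dtype=float) - np.asarray(midbody, dtype=float)
    r = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore"):
        phi = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
    n = len(r)
    dr = np.full(n, np.nan)
    dphi = np.full(n, np.nan)
    dr[1:-1] = (r[2:] - r[:-2]) * fps / 2.0
    step = wrap_angle_deg(np.diff(phi))           # (n-1,) Phi steps
    dphi[1:-1] = (step[1:] + step[:-1]) * fps / 2.0
    dphi[r == 0] = np.nan
    return dr, dphi


def quirkiness(a: float | np.ndarray, A: float | np.ndarray) -> float | np.ndarray:
    """Bounding-box elongation Q = sqrt(1 - a^2/A^2), in [0, 1].

    ``a`` and ``A`` are the minor and major sides of the animal's bounding
    box; Q is 0 for a round shape and 1 for a maximally elongated one.
    """
    a = np.asarray(a, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("major axis A must be positive")
    if np.any((a < 0) | (a > A)):
        raise ValueError("need 0 <= a <= A")
    out = np.sqrt(1.0 - (a / A) ** 2)
    return float(out) if out.ndim == 0 else out


def motion_state(signed_speed: np.ndarray,
                 pause_threshold: float = PAUSE_THRESHOLD_MM_S) -> np.ndarray:
    """Per-frame 'forward' | 'reverse' | 'pause' (or NaN-propagated missing).

    Pause when |speed| < pause_threshold, else the sign decides.
    """
    s = np.asarray(signed_speed, dtype=float)
    out = np.full(s.shape, None, dtype=object)
    ok = np.isfinite(s)
    out[ok & (np.abs(s) < pause_threshold)] = "pause"
    out[ok & (np.abs(s) >= pause_threshold) & (s > 0)] = "forward"
    out[ok & (np.abs(s) >= pause_threshold) & (s <= 0)] = "reverse"
    return out


def _spline_quirkiness(spline: np.ndarray) -> np.ndarray:
    T = len(spline)
    out = np.full(T, np.nan)
    for t in range(T):
        pts = spline[t]
        if not np.isfinite(pts).all():
            continue
        a, A = min_area_bounding_box(pts)
        if A > 0:
            out[t] = quirkiness(a, A)
    return out


def compute_frame_features(trajectory: Trajectory) -> pd.DataFrame:
    """All frame-level features for one animal, one row per frame.

    Invisible frames are NaN throughout. The ``on_lawn`` column is added
    later by the lawn module once a lawn polygon is available.
    """
    if not trajectory.oriented:
        raise ValueError("trajectory must be head/tail oriented")
    spline = trajectory.spline.copy()
    spline[~trajectory.visible] = np.nan
    head, midbody = body_part_centroids(spline)
    centroid = trajectory.centroid.copy()
    centroid[~trajectory.visible] = np.nan
    fps = trajectory.fps

    # local tail-to-head axis at the midbody (point 17 minus point 33, 1-based)
    axis = spline[:, 16, :] - spline[:, 32, :]
    nrm = np.linalg.norm(axis, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    axis = axis / nrm

    mid_speed = signed_midbody_speed(midbody, axis, fps)
    dr, dphi = head_motion_relative_to_midbody(head, midbody, fps)

    df = pd.DataFrame({
        "frame": np.arange(trajectory.n_frames),
        "time_s": trajectory.time_s,
        "visible": trajectory.visible,
        "midbody_speed": mid_speed,
        "midbody_angular_speed": angular_speed(midbody, fps),
        "head_speed": path_speed(head, fps),
        "head_angular_speed": angular_speed(head, fps),
        "head_radial_velocity": dr,
        "head_angular_velocity": dphi,
        "quirkiness": _spline_quirkiness(spline),
        "centroid_speed": path_speed(centroid, fps),
        "centroid_angular_speed": angular_speed(centroid, fps),
    })
    df["motion_state"] = motion_state(mid_speed.astype(float))
    return df


def bin_features(frame_features: pd.DataFrame, fps: float, bin_s: float = 10.0,
                 missing_ceiling: float = 0.5,
                 on_lawn: np.ndarray | None = None) -> pd.DataFrame:
    """Aggregate frame features into contiguous 10-s bins.

    Bins are ``fps * bin_s`` frames, anchored at the first row; a trailing
    partial bin is dropped. Per-bin means ignore missing frames; a bin whose
    missing fraction exceeds ``missing_ceiling`` is marked missing wholesale
    (all feature columns NaN, ``missing_frac`` retained).
    """
    bin_frames = int(round(fps * bin_s))
    if bin_frames <= 0:
        raise ValueError("bin_s * fps must be >= 1 frame")
    n = len(frame_features)
    if n < bin_frames:
        raise ValueError("series shorter than one bin")
    n_bins = n // bin_frames
    df = frame_features.iloc[: n_bins * bin_frames]
    idx = np.repeat(np.arange(n_bins), bin_frames)

    speed = df["midbody_speed"].to_numpy(dtype=float)
    ms = df["motion_state"].to_numpy(dtype=object)
    valid = np.isfinite(speed)
    if on_lawn is not None:
        on_lawn = np.asarray(on_lawn, dtype=float)[: n_bins * bin_frames]

    rows = []
    for b in range(n_bins):
        sl = slice(b * bin_frames, (b + 1) * bin_frames)
        sp = speed[sl]
        ok = valid[sl]
        missing_frac = 1.0 - ok.mean()
        st = ms[sl][ok]
        n_ok = ok.sum()
        fwd = sp[ok & (sp >= 0)]
        rev = sp[ok & (sp <= 0)]

        def nmean(col: str) -> float:
            v = df[col].to_numpy(dtype=float)[sl]
            v = v[np.isfinite(v)]
            return float(v.mean()) if len(v) else np.nan

        row = {
            "bin": b,
            "t_start_s": df["time_s"].iloc[b * bin_frames],
            "centroid_speed": nmean("centroid_speed"),
            "centroid_angular_speed": nmean("centroid_angular_speed"),
            "frac_forward": float((st == "forward").sum() / n_ok) if n_ok else np.nan,
            "frac_reverse": float((st == "reverse").sum() / n_ok) if n_ok else np.nan,
            "frac_paused": float((st == "pause").sum() / n_ok) if n_ok else np.nan,
            "midbody_forward_speed": float(fwd.mean()) if len(fwd) else np.nan,
            "midbody_reverse_speed": float(rev.mean()) if len(rev) else np.nan,
            "midbody_angular_speed": nmean("midbody_angular_speed"),
            "head_angular_velocity_rel": nmean("head_angular_velocity"),
            "head_radial_velocity_rel": nmean("head_radial_velocity"),
            "missing_frac": missing_frac,
        }
        if on_lawn is not None:
            ol = on_lawn[sl]
            ol = ol[np.isfinite(ol)]
            row["on_lawn_frac"] = float(ol.mean()) if len(ol) else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    bad = out["missing_frac"] > missing_ceiling
    feature_cols = [c for c in out.columns
                    if c not in ("bin", "t_start_s", "missing_frac")]
    out.loc[bad, feature_cols] = np.nan
    return out
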