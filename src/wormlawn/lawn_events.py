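"""Lawn boundary detection, signed distances, boundary-interaction events, QC.

The lawn outline is a closed polygon. The signed head-boundary distance is
positive inside the lawn and negative outside. A head *excursion* is a
maximal run of frames with the head outside, bounded by inside frames; an
excursion that culminates in the whole body (all 49 spline points) exiting
the lawn is a *leaving* event, timestamped at head emergence; the others are
*head pokes*, subtyped by the behavior in the recovery interval (from the
frame of maximal displacement outside to the resumption of forward movement
inside the lawn): reversal if any reverse-motion frame occurs, else pause if
at least half the interval is spent below 0.02 mm/s, else forward.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .core import (
    EVENT_HEAD_POKE_FORWARD,
    EVENT_HEAD_POKE_PAUSE,
    EVENT_HEAD_POKE_REVERSAL,
    EVENT_LEAVING,
    EVENT_REENTRY,
    BoundaryEvent,
    LawnGeometry,
    QCReport,
    Trajectory,
)

__all__ = [
    "detect_lawn_boundary",
    "boundary_distance",
    "body_outside_flags",
    "detect_excursions",
    "Excursion",
    "classify_boundary_events",
    "detect_events",
    "censor_off_lawn",
    "off_lawn_frames",
    "apply_qc",
]


def detect_lawn_boundary(background: np.ndarray, pixel_scale: float,
                         origin_mm: tuple[float, float] = (0.0, 0.0),
                         provided: LawnGeometry | None = None,
                         simplify_tol_px: float = 1.0) -> LawnGeometry:
    """Extract the lawn outline from the time-averaged background image.

    Edge detection: Gaussian-smoothed Sobel gradient magnitude localizes the
    lawn edge ring; the closed iso-intensity contour at the midpoint between
    the intensities on either side of the ring is extracted and simplified to
    a polygon in mm. ``provided`` bypasses detection (provenance kept).
    """
    if provided is not None:
        return LawnGeometry(vertices=provided.vertices, provenance="provided")
    from skimage import filters, measure

    img = np.asarray(background, dtype=float)
    smooth = filters.gaussian(img, sigma=2.0, preserve_range=True)
    grad = filters.sobel(smooth)
    edge = grad > max(grad.max() * 0.5, 1e-12)
    if not edge.any() or np.ptp(img) < 1.0:
        raise ValueError("no lawn edge found in background image")
    lo, hi = np.percentile(img, [1, 99])
    level = 0.5 * (lo + hi)
    contours = [c for c in measure.find_contours(smooth, level)
                if np.allclose(c[0], c[-1])]
    if not contours:
        raise ValueError("no closed lawn contour found")
    contour = max(contours, key=len)   # (row, col)
    poly = shapely.Polygon(np.column_stack([contour[:, 1], contour[:, 0]]))
    poly = poly.simplify(simplify_tol_px)
    rc = np.asarray(poly.exterior.coords)[:-1]
    verts_mm = rc * pixel_scale + np.asarray(origin_mm)
    return LawnGeometry(vertices=verts_mm, provenance="detected")


def boundary_distance(positions: np.ndarray, geometry: LawnGeometry) -> np.ndarray:
    """Signed distance (mm) from each position to the nearest boundary point.

    Positive inside the lawn, negative outside; NaN positions propagate.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    out = np.full(len(pos), np.nan)
    ok = np.isfinite(pos).all(axis=1)
    if ok.any():
        pts = shapely.points(pos[ok, 0], pos[ok, 1])
        dist = shapely.distance(pts, geometry.polygon.exterior)
        inside = shapely.contains_xy(geometry.polygon, pos[ok, 0], pos[ok, 1])
        out[ok] = np.where(inside, dist, -dist)
    return out


def body_outside_flags(trajectory: Trajectory, geometry: LawnGeometry,
                       frames: np.ndarray | None = None) -> np.ndarray:
    """True where every spline point lies outside the lawn; NaN frames False.

    ``frames`` restricts the (comparatively expensive) test to given indices;
    other frames are reported False.
    """
    out = np.zeros(trajectory.n_frames, dtype=bool)
    idx = np.arange(trajectory.n_frames) if frames is None else np.asarray(frames)
    poly = geometry.polygon
    for f in idx:
        sp = trajectory.spline[f]
        if not np.isfinite(sp).all():
            continue
        out[f] = not shapely.contains_xy(poly, sp[:, 0], sp[:, 1]).any()
    return out


@dataclass(frozen=True)
class Excursion:
    """A candidate head excursion: maximal run of head-outside frames."""

    start: int            # first frame with head outside
    peak: int             # most-negative-distance frame
    end: int              # first frame with head back inside (exclusive run end)
    peak_distance: float
    returned: bool        # False if the run hits the end of the series
    interrupted: bool = False   # touches missing frames: leaving-candidate only


def detect_excursions(distance: np.ndarray, visible: np.ndarray | None = None,
                      min_depth_mm: float = 0.01) -> list[Excursion]:
    """Maximal runs of negative head-boundary distance.

    Runs shallower than ``min_depth_mm`` are ignored as sub-pixel boundary
    noise. Missing frames flanked by outside frames are bridged into the run,
    and a run that contains or borders missing frames is flagged
    ``interrupted``: it is void as a head-poke candidate (its recovery cannot
    be scored without guessing) but remains a leaving candidate, since a
    full-body exit is decided by the observed frames alone. A run that
    reaches the end of the series without returning is reported with
    ``returned=False`` (likewise a leaving candidate only).
    """
    d = np.asarray(distance, dtype=float)
    n = len(d)
    missing = ~np.isfinite(d)
    if visible is not None:
        missing |= ~np.asarray(visible, dtype=bool)
    neg = np.zeros(n, dtype=bool)
    neg[~missing] = d[~missing] < 0
    out: list[Excursion] = []
    t = 0
    combined = neg | missing
    while t < n:
        if not combined[t]:
            t += 1
            continue
        start = t
        while t < n and combined[t]:
            t += 1
        end = t
        obs = start + np.flatnonzero(neg[start:end])
        if len(obs) == 0:           # purely missing stretch: not an excursion
            continue
        start, end = int(obs[0]), int(obs[-1]) + 1
        interrupted = missing[start:end].any() \
            or (start > 0 and missing[start - 1]) \
            or (end < n and missing[end])
        peak = start + int(np.nanargmin(d[start:end]))
        if -d[peak] < min_depth_mm:
            continue
        out.append(Excursion(start=start, peak=peak, end=end,
                             peak_distance=float(d[peak]), returned=end < n,
                             interrupted=bool(interrupted)))
    return out


def classify_boundary_events(excursions: list[Excursion], body_outside: np.ndarray,
                             body_inside: np.ndarray, motion: np.ndarray,
                             fps: float,
                             recovery_cap_s: float = 30.0) -> list[BoundaryEvent]:
    """Turn head excursions into classified boundary events.

    ``body_outside`` / ``body_inside`` flag frames where all 49 spline points
    are outside / inside the lawn; ``motion`` is the per-frame motion state
    ('forward' | 'reverse' | 'pause' | None). Subtype priority when criteria
    co-occur: reversal > pause > forward.
    """
    n = len(body_outside)
    events: list[BoundaryEvent] = []
    for exc in excursions:
        full_exit = np.flatnonzero(body_outside[exc.start:exc.end])
        if len(full_exit):
            exit_frame = exc.start + int(full_exit[0])
            peak = min(max(exc.peak, exc.start), exit_frame)
            events.append(BoundaryEvent(EVENT_LEAVING, exc.start, peak,
                                        exit_frame, exc.peak_distance))
            # re-entry: first frame the whole body is back inside
            scan = np.flatnonzero(body_inside[exit_frame:])
            if len(scan):
                f2 = exit_frame + int(scan[0])
                events.append(BoundaryEvent(EVENT_REENTRY, f2, f2, f2, 0.0))
            continue
        if not exc.returned or exc.interrupted:
            continue
        # head poke: recovery runs from the peak to resumed forward motion
        # inside the lawn, capped to bound degenerate recoveries
        cap = exc.peak + 1 + int(round(recovery_cap_s * fps))
        rec_end = None
        for f in range(exc.end, min(cap, n)):
            if motion[f] == "forward":
                rec_end = f
                break
        if rec_end is None:
            rec_end = min(cap, n)
        rec = motion[exc.peak + 1:rec_end]
        rec_obs = [m for m in rec if m is not None]
        if any(m == "reverse" for m in rec_obs):
            etype = EVENT_HEAD_POKE_REVERSAL
        elif rec_obs and sum(m == "pause" for m in rec_obs) >= 0.5 * len(rec_obs):
            etype = EVENT_HEAD_POKE_PAUSE
        else:
            etype = EVENT_HEAD_POKE_FORWARD
        events.append(BoundaryEvent(etype, exc.start, exc.peak, exc.end,
                                    exc.peak_distance))
    events.sort(key=lambda e: (e.start_frame, e.end_frame))
    return events


def detect_events(trajectory: Trajectory, geometry: LawnGeometry,
                  frame_features: pd.DataFrame,
                  min_depth_mm: float | None = None,
                  recovery_cap_s: float = 30.0) -> list[BoundaryEvent]:
    """End-to-end event detection for one animal.

    Computes the signed head distance, finds excursions, evaluates whole-body
    containment only where needed, and classifies. ``min_depth_mm`` defaults
    to one pixel if the trajectory carries a pixel scale, else 0.01 mm.
    """
    if min_depth_mm is None:
        min_depth_mm = trajectory.pixel_scale or 0.01
    d = boundary_distance(trajectory.head(), geometry)
    excursions = detect_excursions(d, trajectory.visible, min_depth_mm)
    # whole-body tests only on and after head-outside runs
    check = set()
    for exc in excursions:
        check.update(range(exc.start, exc.end))
    body_out = body_outside_flags(trajectory, geometry,
                                  frames=np.asarray(sorted(check), dtype=int))
    # body-inside flags are needed after full exits, scanned forward lazily
    body_in = np.zeros(trajectory.n_frames, dtype=bool)
    poly = geometry.polygon
    for exc in excursions:
        if not body_out[exc.start:exc.end].any():
            continue
        exit_frame = exc.start + int(np.flatnonzero(body_out[exc.start:exc.end])[0])
        for f in range(exit_frame, trajectory.n_frames):
            sp = trajectory.spline[f]
            if np.isfinite(sp).all() and \
                    shapely.contains_xy(poly, sp[:, 0], sp[:, 1]).all():
                body_in[f] = True
                break
    motion = frame_features["motion_state"].to_numpy(dtype=object)
    return classify_boundary_events(excursions, body_out, body_in, motion,
                                    trajectory.fps, recovery_cap_s)


def off_lawn_frames(events: list[BoundaryEvent], n_frames: int) -> np.ndarray:
    """Boolean mask of frames between each leaving and the following re-entry.

    A final unresolved leaving censors through the end of the series.
    """
    mask = np.zeros(n_frames, dtype=bool)
    start = None
    for e in sorted(events, key=lambda e: e.start_frame):
        if e.type == EVENT_LEAVING:
            start = e.start_frame
        elif e.type == EVENT_REENTRY and start is not None:
            mask[start:e.start_frame] = True
            start = None
    if start is not None:
        mask[start:] = True
    return mask


def censor_off_lawn(frame_features: pd.DataFrame,
                    off_lawn: np.ndarray) -> pd.DataFrame:
    """Mark off-lawn frames missing for all state-model inputs (idempotent).

    Adds/updates an ``on_lawn`` column (1 on lawn, 0 off) and NaNs every
    feature column on off-lawn frames.
    """
    out = frame_features.copy()
    off = np.asarray(off_lawn, dtype=bool)
    feature_cols = [c for c in out.columns
                    if c not in ("frame", "time_s", "visible", "on_lawn")]
    numeric = [c for c in feature_cols if c != "motion_state"]
    out.loc[off, numeric] = np.nan
    if "motion_state" in out.columns:
        out.loc[off, "motion_state"] = None
    out["on_lawn"] = np.where(out["visible"].to_numpy(dtype=bool),
                              (~off).astype(float), np.nan)
    return out


QC_VISIBLE = "visible_lt_half"
QC_ON_LAWN = "not_on_lawn_1min_in_first_20min"
QC_BUMP = "plate_bumped"


def apply_qc(trajectory: Trajectory, on_lawn: np.ndarray, bumped: bool = False,
             expected_duration_s: float = 3600.0,
             analysis_tail_s: float = 2400.0) -> tuple[QCReport, Trajectory]:
    """Per-animal inclusion rules and truncation to the analysis window.

    Rules: (1) visible for at least half the expected recording (cumulatively
    30 min of a 1-h assay); (2) on the lawn for at least one minute within
    the first 20 min; (3) the plate was not bumped (an input flag). A shorter
    recording scales the rules pro-rata (with a warning). The returned
    trajectory is the final ``analysis_tail_s`` (40 min) for downstream use.
    """
    import warnings

    n = trajectory.n_frames
    fps = trajectory.fps
    actual_s = n / fps
    scale = 1.0
    if actual_s < expected_duration_s - 0.5 / fps:
        scale = actual_s / expected_duration_s
        warnings.warn(
            f"recording is {actual_s:.0f}s < expected {expected_duration_s:.0f}s; "
            "QC rules scaled pro-rata", stacklevel=2)
    reasons = []
    if trajectory.visible.sum() / fps < 0.5 * expected_duration_s * scale:
        reasons.append(QC_VISIBLE)
    first = int(round(min(1200.0 * scale, actual_s) * fps))
    ol = np.asarray(on_lawn, dtype=float)[:first]
    if np.nansum(ol) / fps < 60.0 * scale:
        reasons.append(QC_ON_LAWN)
    if bumped:
        reasons.append(QC_BUMP)
    report = QCReport(animal_id=trajectory.animal_id,
                      passed=not reasons, reasons=reasons)
    tail = int(round(analysis_tail_s * scale * fps))
    return report, trajectory.slice_frames(max(n - tail, 0), n)
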