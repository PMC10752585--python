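"""Single-worm tracking: grayscale movie stack -> 49-point spline trajectory.

Pipeline per movie:

1. background estimation as the per-pixel temporal median (the worm moves,
   the plate does not);
2. per-frame segmentation of the worm as the largest dark (background-minus-
   frame) connected component, with an area floor rejecting specks;
3. centroid smoothing with a constant-velocity Kalman filter with gating, so
   brief missed detections coast instead of dropping out;
4. skeletonization of the worm mask, extraction of the longest endpoint-to-
   endpoint path of the skeleton graph, and a smoothing-spline resample to
   49 evenly spaced points from one end of the body to the other;
5. head/tail assignment: per-frame flips are resolved by continuity with the
   previous frame, then the global orientation is chosen so the head end
   shows the larger cumulative displacement (the head of a crawling worm
   moves more than the tail).
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.interpolate import splev, splprep
from scipy.ndimage import binary_fill_holes
from skimage.filters import gaussian
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize

from .core import N_SPLINE, Trajectory

__all__ = [
    "estimate_background",
    "segment_worm",
    "Detection",
    "track_positions",
    "fit_spline",
    "assign_head_tail",
    "track_movie",
]


def estimate_background(stack: np.ndarray, max_frames: int = 200) -> np.ndarray:
    """Per-pixel temporal median over up to ``max_frames`` evenly spaced frames."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a (T, H, W) stack")
    idx = np.linspace(0, len(stack) - 1, min(max_frames, len(stack))).astype(int)
    return np.median(stack[idx].astype(float), axis=0)


@dataclass
class Detection:
    """One segmented worm: mask, centroid (row, col) and area in pixels."""

    mask: np.ndarray
    centroid_px: tuple[float, float]     # (row, col)
    area_px: int


def segment_worm(frame: np.ndarray, background: np.ndarray,
                 threshold: float = 20.0,
                 min_area_px: int | None = None) -> Detection | None:
    """Largest dark blob of ``background - frame``, or None if nothing passes.

    ``threshold`` is the minimum darkening (intensity units) relative to the
    background; ``min_area_px`` rejects blobs smaller than a speck (callers
    typically pass 25% of the median worm area over the movie). The centroid
    is the darkening-weighted center of mass (sub-pixel).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    diff = np.asarray(background, dtype=float) - np.asarray(frame, dtype=float)
    rough = diff > threshold
    if not rough.any():
        return None
    lab = label(rough)
    best = max(regionprops(lab), key=lambda r: r.area)
    if min_area_px is not None and best.area < min_area_px:
        return None
    # refine within a padded crop: smoothing softens the blob edge so the
    # weighted centroid is sub-pixel
    r0, c0, r1, c1 = best.bbox
    pad = 5
    r0, c0 = max(r0 - pad, 0), max(c0 - pad, 0)
    r1, c1 = min(r1 + pad, diff.shape[0]), min(c1 + pad, diff.shape[1])
    crop = gaussian(diff[r0:r1, c0:c1], sigma=1.0, preserve_range=True)
    cmask = crop > threshold
    clab = label(cmask)
    cbest = max(regionprops(clab, intensity_image=np.clip(crop, 0.0, None)),
                key=lambda r: r.area)
    worm = np.zeros(diff.shape, dtype=bool)
    worm[r0:r1, c0:c1] = binary_fill_holes(clab == cbest.label)
    cy, cx = cbest.centroid_weighted
    return Detection(mask=worm, centroid_px=(cy + r0, cx + c0),
                     area_px=int(cbest.area))


def track_positions(measurements: np.ndarray, fps: float,
                    process_noise: float = 0.05,
                    measurement_noise: float = 0.01,
                    gate_sigma: float = 5.0,
                    max_coast: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Constant-velocity Kalman filter over 2-D positions with gating.

    ``measurements`` is (T, 2) with NaN rows for missed detections; units are
    arbitrary but ``process_noise`` (accel std per second) and
    ``measurement_noise`` (position std) must match them. Measurements whose
    Mahalanobis innovation exceeds ``gate_sigma`` are rejected (treated as
    missing). Missing/rejected frames get the predicted-only position and are
    flagged untracked; after ``max_coast`` consecutive misses the filter
    re-initializes on the next in-gate measurement. Returns (positions
    (T, 2), tracked mask (T,)); frames before the first detection are NaN,
    and an all-NaN input is an error.
    """
    z = np.asarray(measurements, dtype=float)
    if not np.isfinite(z).all(axis=1).any():
        raise ValueError("no valid measurements in any frame")
    T = len(z)
    dt = 1.0 / fps
    F = np.eye(4)
    F[0, 2] = F[1, 3] = dt
    q = process_noise ** 2
    G = np.array([[0.5 * dt ** 2, 0], [0, 0.5 * dt ** 2], [dt, 0], [0, dt]])
    Qm = G @ G.T * q
    H = np.zeros((2, 4))
    H[0, 0] = H[1, 1] = 1.0
    R = np.eye(2) * measurement_noise ** 2

    out = np.full((T, 2), np.nan)
    tracked = np.zeros(T, dtype=bool)
    x = None
    P = None
    misses = 0
    for t in range(T):
        have = np.isfinite(z[t]).all()
        if x is None:
            if have:
                x = np.array([z[t, 0], z[t, 1], 0.0, 0.0])
                P = np.diag([measurement_noise ** 2] * 2 + [1.0] * 2)
                out[t] = x[:2]
                tracked[t] = True
            continue
        # predict
        x = F @ x
        P = F @ P @ F.T + Qm
        accepted = False
        if have:
            S = H @ P @ H.T + R
            innov = z[t] - H @ x
            maha2 = float(innov @ np.linalg.solve(S, innov))
            if maha2 <= gate_sigma ** 2:
                Kg = P @ H.T @ np.linalg.inv(S)
                x = x + Kg @ innov
                P = (np.eye(4) - Kg @ H) @ P
                accepted = True
        if accepted:
            misses = 0
            out[t] = x[:2]
            tracked[t] = True
        else:
            misses += 1
            if misses > max_coast:
                # track lost; restart on the next measurement (even if it was
                # outside the stale gate)
                x = None
                if have:
                    x = np.array([z[t, 0], z[t, 1], 0.0, 0.0])
                    P = np.diag([measurement_noise ** 2] * 2 + [1.0] * 2)
                    out[t] = x[:2]
                    tracked[t] = True
                    misses = 0
            else:
                # predicted-only: position reported, frame flagged untracked
                out[t] = x[:2]
    return out, tracked


def _skeleton_path(mask: np.ndarray) -> np.ndarray | None:
    """Longest endpoint-to-endpoint path through the skeleton, as (N, 2)
    (row, col) pixel coordinates; None for degenerate or looped (self-
    overlapping posture) masks."""
    # skeletonize only the mask's bounding box (masks live in large frames)
    nz_r, nz_c = np.nonzero(mask)
    if len(nz_r) == 0:
        return None
    r0, c0 = nz_r.min(), nz_c.min()
    crop = mask[r0:nz_r.max() + 1, c0:nz_c.max() + 1]
    skel = skeletonize(crop)
    rows, cols = np.nonzero(skel)
    rows = rows + r0
    cols = cols + c0
    if len(rows) < 3:
        return None
    nodes = list(zip(rows.tolist(), cols.tolist()))
    node_set = set(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for r, c in nodes:
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            nb = (r + dr, c + dc)
            if nb not in node_set:
                continue
            if dr and dc and ((r, c + dc) in node_set or (r + dr, c) in node_set):
                continue      # diagonal shortcut of an orthogonal corner
            g.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    # restrict to the largest connected component
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp)
    if g.number_of_edges() >= g.number_of_nodes():
        return None           # skeleton contains a loop: coiled posture
    ends = [n for n in g.nodes if g.degree(n) == 1]
    if len(ends) < 2:
        return None
    # two passes of Dijkstra from an endpoint find the tree diameter
    src = ends[0]
    dist = nx.single_source_dijkstra_path_length(g, src, weight="weight")
    far = max(dist, key=dist.get)
    dist2, paths = nx.single_source_dijkstra(g, far, weight="weight")
    far2 = max(dist2, key=dist2.get)
    path = paths[far2]
    if len(path) < 3:
        return None
    return np.asarray(path, dtype=float)


def fit_spline(mask: np.ndarray, n_points: int = N_SPLINE,
               smoothing: float = 5.0) -> np.ndarray | None:
    """Smoothing spline through the skeleton path, resampled to ``n_points``
    evenly spaced points; (n_points, 2) in (row, col) pixels, or None."""
    path = _skeleton_path(mask)
    if path is None:
        return None
    # drop duplicate consecutive pixels (splprep requires strictly moving u)
    keep = np.r_[True, np.linalg.norm(np.diff(path, axis=0), axis=1) > 0]
    path = path[keep]
    if len(path) < 4:
        return None
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    u = np.r_[0.0, np.cumsum(seg)]
    u /= u[-1]
    k = min(3, len(path) - 1)
    tck, _ = splprep([path[:, 0], path[:, 1]], u=u, s=smoothing, k=k)
    uu = np.linspace(0.0, 1.0, n_points)
    rr, cc = splev(uu, tck)
    return np.stack([rr, cc], axis=1)


def assign_head_tail(splines: np.ndarray,
                     max_bridge: int = 2) -> tuple[np.ndarray, bool]:
    """Orient splines so index 0 is the head.

    Endpoint identity is kept by continuity: within runs of valid frames
    (gaps of at most ``max_bridge`` invalid frames are bridged) each spline is
    flipped to stay closest, point for point, to the previous oriented frame.
    Longer gaps (coiled/omega-turn postures, where the animal can reorient in
    place) break identity, so each run is oriented independently: crawling
    worms lead with the head, so a run is flipped to make the mean projection
    of the body-centroid velocity onto the tail-to-head axis positive. Runs
    whose evidence is weak (little travel, or projection near zero) inherit
    the orientation of their best-matching neighbor run. ``ambiguous`` is
    True when no run carries decisive motion evidence (e.g. a stationary
    animal).
    """
    S = np.asarray(splines, dtype=float).copy()
    valid = np.isfinite(S).all(axis=(1, 2))
    idx = np.flatnonzero(valid)
    if len(idx) < 2:
        return S, True
    body_len = float(np.median(
        np.linalg.norm(np.diff(S[idx], axis=1), axis=2).sum(axis=1)))

    # split valid frames into identity runs at long invalid gaps
    runs: list[list[int]] = [[int(idx[0])]]
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a > max_bridge + 1:
            runs.append([])
        runs[-1].append(int(b))

    # continuity within each run
    for run in runs:
        for a, b in zip(run[:-1], run[1:]):
            d_same = np.linalg.norm(S[b] - S[a], axis=1).sum()
            d_flip = np.linalg.norm(S[b, ::-1] - S[a], axis=1).sum()
            if d_flip < d_same:
                S[b] = S[b, ::-1]

    # per-run orientation: head leads the motion
    scores, travels = [], []
    for run in runs:
        score = travel = 0.0
        for a, b in zip(run[:-1], run[1:]):
            step = S[b].mean(axis=0) - S[a].mean(axis=0)
            axis = S[a, 0] - S[a, -1]
            nrm = np.linalg.norm(axis)
            if nrm > 0:
                score += float(step @ axis / nrm)
            travel += float(np.linalg.norm(step))
        if score < 0:
            for t in run:
                S[t] = S[t, ::-1]
            score = -score
        scores.append(score)
        travels.append(travel)

    decisive = [s > 0.05 * body_len and (tr == 0 or s > 0.2 * tr)
                for s, tr in zip(scores, travels)]
    if not any(decisive):
        return S, True
    # weak runs inherit orientation from the nearest decisive run by
    # whole-body flip matching across the gap
    for i, run in enumerate(runs):
        if decisive[i]:
            continue
        j = min((j for j in range(len(runs)) if decisive[j]),
                key=lambda j: abs(j - i))
        ref = S[runs[j][-1]] if j < i else S[runs[j][0]]
        probe = S[run[0]] if j < i else S[run[-1]]
        if np.linalg.norm(probe[::-1] - ref, axis=1).sum() < \
                np.linalg.norm(probe - ref, axis=1).sum():
            for t in run:
                S[t] = S[t, ::-1]
    return S, False


def track_movie(stack: np.ndarray, fps: float, pixel_scale: float,
                origin_mm: tuple[float, float] = (0.0, 0.0),
                threshold: float = 20.0, animal_id: str = "tracked",
                ) -> Trajectory:
    """Full tracking pipeline: stack -> oriented 49-point Trajectory (mm).

    Pixel (row, col) coordinates map to mm as x = origin_mm[0] + col *
    pixel_scale, y = origin_mm[1] + row * pixel_scale (matching the rendering
    convention). Frames with no accepted detection are invisible.
    """
    stack = np.asarray(stack)
    T = len(stack)
    background = estimate_background(stack)

    detections: list[Detection | None] = []
    areas = []
    for t in range(T):
        det = segment_worm(stack[t], background, threshold=threshold)
        detections.append(det)
        if det is not None:
            areas.append(det.area_px)
    if not areas:
        raise ValueError("no worm detected in any frame")
    floor = 0.25 * float(np.median(areas))
    for t, det in enumerate(detections):
        if det is not None and det.area_px < floor:
            detections[t] = None

    meas = np.full((T, 2), np.nan)
    for t, det in enumerate(detections):
        if det is not None:
            meas[t] = det.centroid_px
    # worm accelerations (direction reversals within a frame or two) dwarf the
    # sub-pixel measurement noise, so the filter mostly trusts measurements
    filtered, tracked = track_positions(
        meas, fps, process_noise=0.9 / pixel_scale,
        measurement_noise=0.8, gate_sigma=6.0)

    splines_px = np.full((T, N_SPLINE, 2), np.nan)
    for t, det in enumerate(detections):
        if det is None or not tracked[t]:
            continue
        sp = fit_spline(det.mask)
        if sp is not None:
            splines_px[t] = sp
    # a skeleton path much shorter than the animal means a partly occluded or
    # self-overlapping posture; flag those frames invalid
    seg_len = np.linalg.norm(np.diff(splines_px, axis=1), axis=2).sum(axis=1)
    good = np.isfinite(seg_len)
    if good.any():
        median_len = float(np.median(seg_len[good]))
        splines_px[good & (seg_len < 0.8 * median_len)] = np.nan
    splines_px, ambiguous = assign_head_tail(splines_px)

    visible = np.isfinite(splines_px).all(axis=(1, 2))
    spline_mm = np.full_like(splines_px, np.nan)
    spline_mm[..., 0] = origin_mm[0] + splines_px[..., 1] * pixel_scale  # x from col
    spline_mm[..., 1] = origin_mm[1] + splines_px[..., 0] * pixel_scale  # y from row
    centroid = np.full((T, 2), np.nan)
    centroid[tracked, 0] = origin_mm[0] + filtered[tracked, 1] * pixel_scale
    centroid[tracked, 1] = origin_mm[1] + filtered[tracked, 0] * pixel_scale
    visible &= tracked

    return Trajectory(
        fps=fps, time_s=np.arange(T) / fps, visible=visible,
        spline=spline_mm, centroid=centroid, pixel_scale=pixel_scale,
        animal_id=animal_id, oriented=True, orientation_ambiguous=ambiguous)
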