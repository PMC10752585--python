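"""Small geometry helpers: minimum-area bounding boxes and rigid transforms."""
from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull


def min_area_bounding_box(points: np.ndarray) -> tuple[float, float]:
    """Minor and major side lengths of the minimum-area rotated rectangle.

    Uses the rotating-calipers property: the optimal rectangle has one side
    collinear with a convex-hull edge. ``points`` is (N, 2); returns (a, A)
    with a <= A. Degenerate (collinear) inputs give a = 0.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[np.isfinite(pts).all(axis=1)]
    if len(pts) == 0:
        raise ValueError("no finite points")
    if len(pts) == 1:
        return 0.0, 0.0
    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except Exception:
        # collinear points: extent along the principal direction
        d = pts - pts.mean(axis=0)
        span = np.linalg.norm(d.max(axis=0) - d.min(axis=0))
        return 0.0, float(span)
    edges = np.diff(np.vstack([hp, hp[:1]]), axis=0)
    ang = np.mod(np.arctan2(edges[:, 1], edges[:, 0]), np.pi / 2)
    c, s = np.cos(ang), np.sin(ang)                     # (M,)
    x = c[:, None] * hp[None, :, 0] + s[:, None] * hp[None, :, 1]
    y = -s[:, None] * hp[None, :, 0] + c[:, None] * hp[None, :, 1]
    w = x.max(axis=1) - x.min(axis=1)
    h = y.max(axis=1) - y.min(axis=1)
    i = int(np.argmin(w * h))
    return (float(min(w[i], h[i])), float(max(w[i], h[i])))


def rigid_transform(points: np.ndarray, angle_rad: float = 0.0,
                    offset: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Rotate then translate an (..., 2) array of points."""
    pts = np.asarray(points, dtype=float)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[c, -s], [s, c]])
    return pts @ rot.T + np.asarray(offset, dtype=float)


def wrap_angle_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)
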