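"""Deterministic, hand-traceable boundary-event choreographies.

Each builder returns (trajectory, expected_events) where the expected event
frames are derived here with plain-numpy circle geometry (independent of the
package's shapely-based detector): the head-segment centroid sits
``HEAD_BACK`` mm behind the tip along the body axis, and the signed distance
to a circular lawn of radius R centered at the origin is R - |position|.
"""
from __future__ import annotations

import numpy as np

from wormlawn import (
    EVENT_HEAD_POKE_FORWARD,
    EVENT_HEAD_POKE_PAUSE,
    EVENT_HEAD_POKE_REVERSAL,
    EVENT_LEAVING,
    EVENT_REENTRY,
    LawnGeometry,
)
from wormlawn.synth import rigid_worm_trajectory

R = 1.5
FPS = 3.0
#: head-segment centroid (mean of spline points 1-8) sits this far behind the
#: tip: mean(k * L/48 for k in 0..7) with L = 1 mm
HEAD_BACK = 3.5 / 48.0


def lawn() -> LawnGeometry:
    return LawnGeometry.disk((0.0, 0.0), R, n_vertices=256)


def _expected_pokes(tip: np.ndarray, axis: np.ndarray, poke_type: str):
    """Excursion [start, peak, end) triples of the head-segment centroid."""
    hc = tip - HEAD_BACK * axis / np.linalg.norm(axis, axis=1, keepdims=True)
    d = R - np.linalg.norm(hc, axis=1)
    out = d < 0
    events = []
    t, n = 0, len(d)
    while t < n:
        if not out[t]:
            t += 1
            continue
        start = t
        while t < n and out[t]:
            t += 1
        if t == n:
            break                      # unreturned trailing run: no poke
        peak = start + int(np.argmin(d[start:t]))
        events.append((poke_type, start, peak, t))
    return events


def reversal_pokes(n_cycles: int = 3):
    """Straight dashes out along +x, returning by backing up (reverse)."""
    xs = [1.30]
    for _ in range(n_cycles):
        while xs[-1] - HEAD_BACK < R + 0.10:        # dash out
            xs.append(xs[-1] + 0.05)
        while xs[-1] - HEAD_BACK > R - 0.30:        # back in (reversal)
            xs.append(xs[-1] - 0.05)
    for _ in range(6):                              # resume forward inside
        xs.append(xs[-1] + 0.05)
    tip = np.column_stack([xs, np.zeros(len(xs))])
    axis = np.tile([[1.0, 0.0]], (len(xs), 1))
    traj = rigid_worm_trajectory(tip, axis, fps=FPS)
    return traj, _expected_pokes(tip, axis, EVENT_HEAD_POKE_REVERSAL)


def _arc_sweep(depth: float, n_loops: int, pause_frames: int = 0):
    """Tip circles an off-center loop whose far side pokes out of the lawn.

    The tip always moves forward along the tangent; with ``pause_frames`` it
    freezes at the deepest point of each loop.  The body axis is tilted
    outward from the lawn center so only the head pokes out while the tail
    stays well inside (motion still projects forward onto the axis).
    """
    c, rho = 0.9, R + depth - 0.9                   # loop center and radius
    step = 0.05 / rho                               # 0.05 mm per frame
    angles = []
    for _ in range(n_loops):
        th = -np.pi                                 # start on the inside
        while th < np.pi:
            angles.append(th)
            if pause_frames and -step / 2 <= th < step / 2:
                angles.extend([th] * pause_frames)  # freeze at deepest point
            th += step
    th = np.asarray(angles)
    tip = np.column_stack([c + rho * np.cos(th), rho * np.sin(th)])
    tangent = np.column_stack([-np.sin(th), np.cos(th)])  # direction of motion
    outward = tip / np.linalg.norm(tip, axis=1, keepdims=True)
    axis = 0.6 * tangent + 0.8 * outward
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    return tip, axis


def forward_pokes(n_loops: int = 3):
    tip, axis = _arc_sweep(depth=0.18, n_loops=n_loops)
    traj = rigid_worm_trajectory(tip, axis, fps=FPS)
    return traj, _expected_pokes(tip, axis, EVENT_HEAD_POKE_FORWARD)


def pause_pokes(n_loops: int = 3):
    tip, axis = _arc_sweep(depth=0.10, n_loops=n_loops, pause_frames=30)
    traj = rigid_worm_trajectory(tip, axis, fps=FPS)
    return traj, _expected_pokes(tip, axis, EVENT_HEAD_POKE_PAUSE)


def leavings(n_cycles: int = 3):
    """Deep straight dashes fully off the lawn, then straight back in."""
    xs = [1.20]
    for _ in range(n_cycles):
        while xs[-1] - 1.0 < R + 0.05:              # until the tail is out
            xs.append(xs[-1] + 0.06)
        while xs[-1] > 1.20:                        # back in until well inside
            xs.append(xs[-1] - 0.06)
    tip = np.column_stack([xs, np.zeros(len(xs))])
    axis = np.tile([[1.0, 0.0]], (len(xs), 1))
    traj = rigid_worm_trajectory(tip, axis, fps=FPS)

    x = np.asarray(xs)
    hc = x - HEAD_BACK
    events = []
    t, n = 0, len(x)
    while t < n:
        if not hc[t] > R:
            t += 1
            continue
        start = t
        while t < n and hc[t] > R:
            t += 1
        run = slice(start, t)
        exit_frame = start + int(np.argmax(x[run] - 1.0 > R))
        peak = min(start + int(np.argmax(hc[run])), exit_frame)
        events.append((EVENT_LEAVING, start, peak, exit_frame))
        back = np.flatnonzero(x[exit_frame:] < R)
        if len(back):
            f2 = exit_frame + int(back[0])
            events.append((EVENT_REENTRY, f2, f2, f2))
    return traj, events


def off_lawn_expected(n_cycles: int = 3):
    """The leavings fixture's ground-truth off-lawn frame mask."""
    traj, events = leavings(n_cycles)
    mask = np.zeros(traj.n_frames, dtype=bool)
    start = None
    for etype, s, _, _ in events:
        if etype == EVENT_LEAVING:
            start = s
        elif etype == EVENT_REENTRY and start is not None:
            mask[start:s] = True
            start = None
    if start is not None:
        mask[start:] = True
    return traj, events, mask
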