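import numpy as np
import pandas as pd
import pytest

from wormlawn import (
    PAUSE_THRESHOLD_MM_S,
    angular_speed,
    bin_features,
    compute_frame_features,
    motion_state,
    path_speed,
    quirkiness,
)
from wormlawn.features import (
    head_motion_relative_to_midbody,
    signed_midbody_speed,
)
from wormlawn.synth import rigid_worm_trajectory


def test_path_speed_constant_velocity():
    pos = np.column_stack([np.arange(10) * 0.05, np.zeros(10)])
    v = path_speed(pos, fps=3.0)
    assert np.isnan(v[0]) and np.isnan(v[-1])
    assert np.allclose(v[1:-1], 0.15)


def test_path_speed_missing_neighbor_propagates():
    pos = np.column_stack([np.arange(10) * 0.05, np.zeros(10)])
    pos[4] = np.nan
    v = path_speed(pos, fps=3.0)
    # frames whose centered-difference neighbors are missing go NaN; the
    # missing frame itself still has both neighbors and stays finite
    assert np.isnan(v[3]) and np.isnan(v[5])
    assert np.isfinite(v[2]) and np.isfinite(v[4]) and np.isfinite(v[6])


def test_angular_speed_right_angle_turn():
    pos = np.array([[0.0, 0], [1, 0], [2, 0], [2, 1], [2, 2]])
    a = angular_speed(pos, fps=1.0)
    assert a[1] == pytest.approx(0.0)
    assert a[2] == pytest.approx(90.0)
    assert a[3] == pytest.approx(0.0)


def test_angular_speed_zero_displacement_is_missing():
    pos = np.array([[0.0, 0], [0, 0], [1, 0], [2, 0]])
    a = angular_speed(pos, fps=1.0)
    assert np.isnan(a[1])
    assert a[2] == pytest.approx(0.0)


def test_signed_midbody_speed_reversal_sign():
    mid = np.column_stack([np.r_[np.arange(5), np.arange(5)[::-1][1:]] * 0.1,
                           np.zeros(9)])
    axis = np.tile([[1.0, 0.0]], (9, 1))
    v = signed_midbody_speed(mid, axis, fps=1.0)
    assert np.all(v[1:4] > 0)
    assert np.all(v[5:8] < 0)


def test_head_motion_relative_polar():
    # head circles the midbody at radius 1, quarter turn per frame
    ang = np.arange(8) * np.pi / 2
    head = np.column_stack([np.cos(ang), np.sin(ang)])
    mid = np.zeros((8, 2))
    dr, dphi = head_motion_relative_to_midbody(head, mid, fps=1.0)
    assert np.allclose(dr[1:-1], 0.0, atol=1e-12)
    assert np.allclose(dphi[1:-1], 90.0)


def test_quirkiness_limits():
    assert quirkiness(1.0, 1.0) == pytest.approx(0.0)
    assert quirkiness(0.0, 2.0) == pytest.approx(1.0)
    assert quirkiness(1.0, 2.0) == pytest.approx(np.sqrt(0.75))
    with pytest.raises(ValueError):
        quirkiness(2.0, 1.0)
    with pytest.raises(ValueError):
        quirkiness(1.0, 0.0)


def test_motion_state_threshold():
    v = np.array([0.05, 0.019, -0.019, -0.05, np.nan, PAUSE_THRESHOLD_MM_S])
    s = motion_state(v)
    assert list(s[:4]) == ["forward", "pause", "pause", "reverse"]
    assert s[4] is None
    assert s[5] == "forward"      # exactly at threshold counts as moving


def test_frame_features_straight_crawler():
    T = 30
    tip = np.column_stack([np.arange(T) * 0.05, np.zeros(T)])
    axis = np.tile([[1.0, 0.0]], (T, 1))
    traj = rigid_worm_trajectory(tip, axis, fps=3.0)
    ff = compute_frame_features(traj)
    mid = ff["midbody_speed"].to_numpy()
    assert np.allclose(mid[1:-1], 0.15)
    assert (ff["motion_state"].iloc[1:-1] == "forward").all()
    # straight worm: maximal elongation
    assert (ff["quirkiness"].iloc[1:-1] > 0.999).all()
    assert np.allclose(ff["midbody_angular_speed"].iloc[1:-1], 0.0)


def test_frame_features_requires_orientation(sim_default):
    traj, _, _ = sim_default
    t = traj.slice_frames(0, 30)
    t.oriented = False
    with pytest.raises(ValueError, match="oriented"):
        compute_frame_features(t)


def test_bin_features_shapes_and_missing_rule():
    T = 90      # 3 bins of 30 frames at 3 Hz
    tip = np.column_stack([np.arange(T) * 0.05, np.zeros(T)])
    axis = np.tile([[1.0, 0.0]], (T, 1))
    traj = rigid_worm_trajectory(tip, axis, fps=3.0)
    # second bin: mostly invisible
    traj.visible[35:59] = False
    traj.spline[35:59] = np.nan
    traj.centroid[35:59] = np.nan
    ff = compute_frame_features(traj)
    b = bin_features(ff, fps=3.0, bin_s=10.0)
    assert len(b) == 3
    assert b["centroid_speed"].iloc[0] == pytest.approx(0.15, abs=1e-9)
    assert np.isnan(b["centroid_speed"].iloc[1])     # > 50% missing
    assert b["missing_frac"].iloc[1] > 0.5
    assert np.isfinite(b["centroid_speed"].iloc[2])


def test_bin_features_drops_trailing_partial_bin():
    T = 75
    tip = np.column_stack([np.arange(T) * 0.05, np.zeros(T)])
    axis = np.tile([[1.0, 0.0]], (T, 1))
    traj = rigid_worm_trajectory(tip, axis, fps=3.0)
    b = bin_features(compute_frame_features(traj), fps=3.0, bin_s=10.0)
    assert len(b) == 2


def test_binned_conditional_speeds(analyzed_default):
    b = analyzed_default.binned
    ok = b["midbody_forward_speed"].notna()
    assert (b.loc[ok, "midbody_forward_speed"] >= 0).all()
    ok = b["midbody_reverse_speed"].notna()
    assert (b.loc[ok, "midbody_reverse_speed"] <= 0).all()
    fr = b[["frac_forward", "frac_reverse", "frac_paused"]].dropna()
    assert np.allclose(fr.sum(axis=1), 1.0)
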