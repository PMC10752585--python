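import numpy as np
import pytest

import scripted
from wormlawn import (
    EVENT_LEAVING,
    EVENT_REENTRY,
    QC_BUMP,
    QC_ON_LAWN,
    QC_VISIBLE,
    LawnGeometry,
    apply_qc,
    boundary_distance,
    censor_off_lawn,
    compute_frame_features,
    detect_events,
    detect_excursions,
    off_lawn_frames,
)
from wormlawn.synth import rigid_worm_trajectory


def test_boundary_distance_signed():
    lawn = LawnGeometry.disk((0.0, 0.0), 1.5, n_vertices=256)
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [np.nan, np.nan]])
    d = boundary_distance(pts, lawn)
    assert d[0] == pytest.approx(1.5, abs=1e-3)
    assert d[1] == pytest.approx(0.5, abs=1e-3)
    assert d[2] == pytest.approx(-0.5, abs=1e-3)
    assert np.isnan(d[3])


def test_detect_excursions_rules():
    vis = np.ones(20, dtype=bool)
    d = np.zeros(20) + 0.1
    d[3:6] = -0.05                 # clean excursion
    d[8:10] = -0.002               # too shallow: ignored
    d[12:15] = -0.05               # touches a missing frame: leaving-only
    vis[15] = False
    d[15] = np.nan
    d[18:] = -0.05                 # unreturned terminal run: kept, open
    exc = detect_excursions(d, vis, min_depth_mm=0.01)
    assert len(exc) == 3
    assert (exc[0].start, exc[0].end, exc[0].returned, exc[0].interrupted) \
        == (3, 6, True, False)
    assert (exc[1].start, exc[1].end, exc[1].interrupted) == (12, 15, True)
    assert (exc[2].start, exc[2].end, exc[2].returned) == (18, 20, False)


def test_interrupted_excursion_never_becomes_head_poke():
    # a poke-like run bridged over an interior missing frame yields no event
    vis = np.ones(20, dtype=bool)
    d = np.zeros(20) + 0.1
    d[5:10] = -0.05
    d[7] = np.nan
    vis[7] = False
    exc = detect_excursions(d, vis, min_depth_mm=0.01)
    assert len(exc) == 1 and exc[0].interrupted
    from wormlawn import classify_boundary_events
    ev = classify_boundary_events(
        exc, body_outside=np.zeros(20, dtype=bool),
        body_inside=np.zeros(20, dtype=bool),
        motion=np.array(["forward"] * 20, dtype=object), fps=3.0)
    assert ev == []


@pytest.mark.parametrize("builder", [
    scripted.reversal_pokes, scripted.forward_pokes,
    scripted.pause_pokes, scripted.leavings,
])
def test_scripted_events_detected_exactly(builder):
    traj, expected = builder()
    ff = compute_frame_features(traj)
    det = detect_events(traj, scripted.lawn(), ff)
    assert len(det) == len(expected)
    for (etype, s, p, e), d in zip(expected, det):
        assert d.type == etype
        assert abs(d.start_frame - s) <= 1
        assert abs(d.peak_frame - p) <= 1
        assert abs(d.end_frame - e) <= 1


def test_off_lawn_and_censoring_match_ground_truth():
    traj, expected, mask = scripted.off_lawn_expected()
    ff = compute_frame_features(traj)
    det = detect_events(traj, scripted.lawn(), ff)
    off = off_lawn_frames(det, traj.n_frames)
    assert np.array_equal(off, mask)
    cens = censor_off_lawn(ff, off)
    assert np.array_equal(cens["on_lawn"].to_numpy(), ~mask)
    assert cens.loc[mask, "midbody_speed"].isna().all()
    # on-lawn rows keep whatever the original features held
    on = ~mask
    assert (cens.loc[on, "midbody_speed"].to_numpy()
            == pytest.approx(ff.loc[on, "midbody_speed"].to_numpy(),
                             nan_ok=True))


def _flat_worm(T, fps=3.0):
    tip = np.column_stack([np.full(T, 0.5), np.zeros(T)])
    axis = np.tile([[1.0, 0.0]], (T, 1))
    return rigid_worm_trajectory(tip, axis, fps=fps)


def test_qc_pass_and_tail_truncation():
    T = 3600 * 3
    traj = _flat_worm(T)
    on = np.ones(T, dtype=bool)
    report, tail = apply_qc(traj, on, bumped=False,
                            expected_duration_s=3600, analysis_tail_s=2400)
    assert report.passed and report.reasons == []
    assert tail.n_frames == 2400 * 3
    # the tail is the final 40 minutes
    assert np.allclose(tail.spline[0], traj.spline[T - 2400 * 3])


def test_qc_rejects_low_visibility():
    T = 3600 * 3
    traj = _flat_worm(T)
    traj.visible[: T // 2 + 100] = False
    report, _ = apply_qc(traj, np.ones(T, dtype=bool), bumped=False)
    assert not report.passed
    assert report.reasons == [QC_VISIBLE]


def test_qc_rejects_insufficient_on_lawn_first_20_minutes():
    T = 3600 * 3
    traj = _flat_worm(T)
    on = np.zeros(T, dtype=bool)
    on[: 50 * 3] = True            # only 50 s on lawn in the first 20 min
    on[1200 * 3:] = True           # on lawn afterwards does not count
    report, _ = apply_qc(traj, on, bumped=False)
    assert not report.passed
    assert report.reasons == [QC_ON_LAWN]
    # 61 s on-lawn within the first 20 minutes satisfies the rule
    on2 = np.zeros(T, dtype=bool)
    on2[: 61 * 3] = True
    report2, _ = apply_qc(traj, on2, bumped=False)
    assert report2.passed


def test_qc_rejects_bumped_plate():
    T = 3600 * 3
    traj = _flat_worm(T)
    report, _ = apply_qc(traj, np.ones(T, dtype=bool), bumped=True)
    assert not report.passed
    assert QC_BUMP in report.reasons


def test_qc_multiple_reasons_reported():
    T = 3600 * 3
    traj = _flat_worm(T)
    traj.visible[:] = False
    on = np.zeros(T, dtype=bool)
    report, _ = apply_qc(traj, on, bumped=True)
    assert not report.passed
    assert set(report.reasons) == {QC_VISIBLE, QC_ON_LAWN, QC_BUMP}


def test_leaving_reentry_pairing_on_scripted_fixture():
    traj, expected = scripted.leavings()
    det = detect_events(traj, scripted.lawn(),
                        compute_frame_features(traj))
    types = [d.type for d in det]
    assert types == [EVENT_LEAVING, EVENT_REENTRY] * 3
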