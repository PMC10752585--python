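import numpy as np
import pytest

from wormlawn import (
    N_SPLINE,
    STATE_DWELL,
    STATE_ROAM,
    LawnGeometry,
    SimulationConfig,
    render_movie,
    rigid_worm_trajectory,
    simulate_state_sequence,
    simulate_trajectory,
)
from wormlawn.synth import AGAR_INTENSITY, LAWN_INTENSITY, WORM_INTENSITY


def test_config_validation():
    with pytest.raises(ValueError, match="lawn_radius"):
        SimulationConfig(lawn_radius=-1.0).validate()
    with pytest.raises(ValueError, match="missing_frac"):
        SimulationConfig(missing_frac=1.5).validate()
    with pytest.raises(ValueError, match="roam_speed_mean"):
        SimulationConfig(roam_speed_mean=0.01, dwell_speed_mean=0.03).validate()


def test_state_sequence_reproducible_and_distribution():
    a = simulate_state_sequence(0.8, 0.97, 500, seed=3)
    b = simulate_state_sequence(0.8, 0.97, 500, seed=3)
    assert np.array_equal(a, b)
    assert set(np.unique(a)) <= {STATE_ROAM, STATE_DWELL}
    # stationary roam fraction of this chain is (1-0.97)/(0.2+0.03) ~ 0.13
    many = np.concatenate([
        simulate_state_sequence(0.8, 0.97, 240, seed=s) for s in range(60)])
    frac = np.mean(many == STATE_ROAM)
    assert 0.08 < frac < 0.20


def test_simulated_trajectory_shapes(sim_default):
    traj, lawn, truth = sim_default
    assert traj.spline.shape == (7200, N_SPLINE, 2)
    assert traj.fps == 3.0
    assert len(truth.state_per_bin) == 240
    assert len(truth.state_per_frame) == 7200
    # invisible frames carry NaN coordinates
    assert np.isnan(traj.spline[~traj.visible]).all()
    assert np.isfinite(traj.spline[traj.visible]).all()
    assert isinstance(lawn, LawnGeometry)


def test_simulation_is_deterministic():
    cfg = SimulationConfig(seed=19, duration_s=60.0)
    t1, _, g1 = simulate_trajectory(cfg)
    t2, _, g2 = simulate_trajectory(cfg)
    assert np.array_equal(t1.spline, t2.spline, equal_nan=True)
    assert np.array_equal(g1.state_per_bin, g2.state_per_bin)


def test_body_arc_length_near_one_mm(short_sim):
    traj, _, _ = short_sim
    seg = np.linalg.norm(np.diff(traj.spline, axis=1), axis=2).sum(axis=1)
    assert np.nanmedian(seg) == pytest.approx(1.0, abs=0.1)


def test_speed_separation_by_state(short_sim):
    traj, _, truth = short_sim
    from wormlawn.features import compute_frame_features

    ff = compute_frame_features(traj)
    sp = ff["midbody_speed"].abs().to_numpy()
    roam = truth.state_per_frame == STATE_ROAM
    if roam.any() and (~roam).any():
        assert np.nanmean(sp[roam]) > 2 * np.nanmean(sp[~roam])


def test_rigid_worm_trajectory_geometry():
    tip = np.array([[0.0, 0.0], [0.1, 0.0]])
    axis = np.array([[1.0, 0.0], [1.0, 0.0]])
    traj = rigid_worm_trajectory(tip, axis, fps=3.0)
    assert traj.spline.shape == (2, N_SPLINE, 2)
    # head at the tip, tail one body length behind
    assert np.allclose(traj.spline[0, 0], [0.0, 0.0])
    assert np.allclose(traj.spline[0, -1], [-1.0, 0.0])
    assert np.allclose(traj.spline[1, 0], [0.1, 0.0])


def test_render_movie_intensities_and_origin():
    tip = np.tile([[0.5, 0.0]], (3, 1)) + np.outer(np.arange(3), [0.05, 0.0])
    axis = np.tile([[1.0, 0.0]], (3, 1))
    traj = rigid_worm_trajectory(tip, axis, fps=3.0)
    lawn = LawnGeometry.disk((0.0, 0.0), 1.5)
    mov = render_movie(traj, lawn, pixel_scale=0.01)
    vals = set(np.unique(mov.stack))
    assert vals == {AGAR_INTENSITY, LAWN_INTENSITY, WORM_INTENSITY}
    # the worm's darkest pixels sit at the rendered tip position
    f0 = mov.stack[0]
    rows, cols = np.nonzero(f0 == WORM_INTENSITY)
    cx, rx = mov.to_pixels(traj.centroid[0])
    assert abs(cols.mean() - cx) < 3 and abs(rows.mean() - rx) < 3


def test_render_rejects_out_of_frame_worm():
    tip = np.array([[0.0, 0.0], [50.0, 0.0]])
    axis = np.tile([[1.0, 0.0]], (2, 1))
    traj = rigid_worm_trajectory(tip, axis, fps=3.0)
    lawn = LawnGeometry.disk((0.0, 0.0), 1.5)
    with pytest.raises(ValueError, match="worm out of frame at frame"):
        render_movie(traj, lawn, pixel_scale=0.01,
                     image_size=(300, 300))


def test_ground_truth_events_match_classifier(short_sim):
    """Generator motifs and the event classifier agree on every event type."""
    from wormlawn import analyze_animal

    traj, lawn, truth = short_sim
    res = analyze_animal(traj, lawn)
    for te in truth.events:
        overlapping = [de for de in res.events
                       if de.start_frame <= te.end_frame
                       and de.end_frame >= te.start_frame]
        assert overlapping, f"ground-truth event not detected: {te}"
        assert overlapping[0].type == te.type
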