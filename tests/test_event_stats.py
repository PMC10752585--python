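import numpy as np
import pytest

from wormlawn import (
    EVENT_LEAVING,
    BoundaryEvent,
    align_to_events,
    event_triggered_mean,
    fraction_in_state_before_event,
    leaving_rate_summary,
    logit,
    pre_leaving_acceleration,
    state_at_event,
    state_event_overlap,
)


def _ev(start, peak=None, end=None, etype=EVENT_LEAVING):
    peak = start if peak is None else peak
    end = peak if end is None else end
    return BoundaryEvent(etype, start, peak, end, -0.1 if "poke" in etype
                         or etype == EVENT_LEAVING else 0.0)


def test_align_to_events_window_and_edges():
    series = {"a": np.arange(100, dtype=float)}
    events = {"a": [_ev(10), _ev(2)]}   # second event clips the left edge
    al = align_to_events(series, events, window=(-3, 3))
    assert al.values.shape == (2, 7)
    assert list(al.offsets) == [-3, -2, -1, 0, 1, 2, 3]
    row0 = al.values[0]
    assert np.allclose(row0, np.arange(7, 14))
    row1 = al.values[1]
    assert np.isnan(row1[0])            # offset -3 of event at frame 2 clips
    assert row1[3] == 2.0


def test_align_to_events_align_modes():
    series = {"a": np.arange(50, dtype=float)}
    events = {"a": [_ev(5, peak=8, end=12)]}
    for mode, f in [("start", 5), ("peak", 8), ("end", 12)]:
        al = align_to_events(series, events, window=(0, 0), align=mode)
        assert al.values[0, 0] == f
    with pytest.raises(ValueError):
        align_to_events(series, events, window=(0, 0), align="middle")


def test_event_triggered_mean_masks_columns():
    # 10 events x 5 offsets; columns with >= 10% missing must be masked
    vals = np.zeros((10, 5))
    vals[0, 1] = np.nan                 # 10% missing -> masked
    vals[:5, 2] = np.nan                # 50% missing -> masked
    vals[:, 3] = 7.0                    # complete -> kept
    al_vals = vals
    from wormlawn.event_stats import AlignedMatrix
    al = AlignedMatrix(values=al_vals, offsets=np.arange(-2, 3),
                       event_index=np.arange(10), animal_ids=["a"] * 10)
    mean, n_used = event_triggered_mean(al, max_missing_frac=0.1)
    assert np.isnan(mean[1]) and np.isnan(mean[2])
    assert mean[0] == 0.0 and mean[3] == 7.0 and mean[4] == 0.0
    assert list(n_used) == [10, 9, 5, 10, 10]


def test_fraction_in_state_before_event():
    states = {"a": np.array([1, 1, 0, 0, 0, 1]),
              "b": np.array([1, 0, 0, 1, 1, 1])}
    events = {"a": [4], "b": [2]}
    out = fraction_in_state_before_event(states, events, window_bins=(-2, 0),
                                         state=0)
    at0 = out.loc[out["offset_bins"] == 0, "fraction_in_state"].iloc[0]
    assert at0 == pytest.approx(1.0)    # both events sit in state 0
    at_m2 = out.loc[out["offset_bins"] == -2, "fraction_in_state"].iloc[0]
    assert at_m2 == pytest.approx(0.5)  # a: state 0 at bin 2; b: state 1 at 0
    assert (out["n"] == 2).all()


def test_state_event_overlap_counts():
    states = np.array([0, 0, 1, 1, -1])
    out = state_event_overlap(states, [0, 2, 3, 4], K=2)
    assert out["counts"][0] == 1 and out["counts"][1] == 2
    assert out["unassigned"] == 1
    assert out["fraction"][1] == pytest.approx(2 / 3)


def test_state_at_event_walks_back_over_missing():
    states = np.array([0, 1, -1, -1, -1])
    assert state_at_event(states, 4) == 1
    assert state_at_event(states, 4, max_back_bins=2) == -1
    assert state_at_event(states, 0) == 0
    assert state_at_event(states, 99) == -1


def test_pre_leaving_acceleration_positive_case():
    fps = 3.0
    n = 1200
    speeds, events = {}, {}
    rng = np.random.default_rng(0)
    for i in range(6):
        v = np.full(n, 0.05) + rng.normal(0, 1e-3, n)
        ev_frame = 900
        v[ev_frame - 90: ev_frame] = 0.15          # final 30 s faster
        speeds[f"a{i}"] = v
        events[f"a{i}"] = [_ev(ev_frame)]
    res = pre_leaving_acceleration(speeds, events, fps=fps)
    assert res.n == 6
    assert np.all(res.diff > 0)
    assert res.p_value < 0.01
    assert res.mean_ratio > 2.0


def test_pre_leaving_acceleration_requires_coverage():
    fps = 3.0
    v = np.full(1200, 0.05)
    v[:850] = np.nan                   # baseline window mostly missing
    with pytest.raises(ValueError, match="usable leaving events"):
        pre_leaving_acceleration({"a": v}, {"a": [_ev(900)]}, fps=fps)


def test_logit_clamps_extremes():
    assert logit(0.5, 100) == pytest.approx(0.0)
    lo = logit(0.0, 100)
    hi = logit(1.0, 100)
    eps = 1.0 / 200
    assert lo == pytest.approx(np.log(eps / (1 - eps)))
    assert hi == pytest.approx(-lo)


def test_leaving_rate_summary():
    events = {"a": [_ev(10), _ev(500)], "b": []}
    durations = {"a": 3600.0, "b": 3600.0}
    groups = {"a": "fed", "b": "starved"}
    out = leaving_rate_summary(events, durations, group_per_animal=groups)
    by_g = {s.group: s for s in out}
    assert by_g["fed"].n_events == 2
    assert by_g["fed"].events_per_animal_hour == pytest.approx(2.0)
    assert by_g["fed"].frac_animals_with_event == 1.0
    assert by_g["starved"].events_per_animal_hour == 0.0
    assert by_g["starved"].frac_animals_with_event == 0.0
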