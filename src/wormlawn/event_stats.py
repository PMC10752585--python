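"""Event-aligned statistics: behavior around lawn-boundary events.

Aligns per-frame or per-bin series to event times, computes event-triggered
means with a strict missingness rule, the fraction of animals in a given
state as a function of time before an event, overlap between decoded states
and event frames, the paired pre-leaving speed acceleration, and per-group
leaving-rate summaries with a clamped logit transform.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BoundaryEvent, EVENT_LEAVING

__all__ = [
    "AlignedMatrix",
    "align_to_events",
    "event_triggered_mean",
    "fraction_in_state_before_event",
    "state_at_event",
    "state_event_overlap",
    "pre_leaving_acceleration",
    "PreLeavingResult",
    "EventSummary",
    "leaving_rate_summary",
    "logit",
]


@dataclass
class AlignedMatrix:
    """Event-aligned snippets: one row per event, one column per offset."""

    values: np.ndarray           # (n_events, n_offsets), NaN = missing
    offsets: np.ndarray          # (n_offsets,) offsets in samples rel. to event
    event_index: np.ndarray      # (n_events,) index of the event in its input list
    animal_ids: np.ndarray       # (n_events,) object array

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def offsets_seconds(self, rate_hz: float) -> np.ndarray:
        return self.offsets / float(rate_hz)


def align_to_events(series_per_animal: dict, events_per_animal: dict,
                    window: tuple[int, int], align: str = "start",
                    event_type: str | None = None) -> AlignedMatrix:
    """Stack windows of per-animal series around each event.

    ``series_per_animal`` maps animal id -> 1-D array (frames or bins);
    ``events_per_animal`` maps animal id -> either a list of
    :class:`~wormlawn.core.BoundaryEvent` (aligned at the frame named by
    ``align``: 'start', 'peak' or 'end') or an array of integer sample
    indices. ``window = (lo, hi)`` takes offsets lo..hi inclusive relative to
    the event sample. Samples falling outside the series are NaN.
    """
    lo, hi = int(window[0]), int(window[1])
    if hi < lo:
        raise ValueError("window must satisfy lo <= hi")
    offsets = np.arange(lo, hi + 1)
    rows, idxs, ids = [], [], []
    for animal, events in events_per_animal.items():
        series = np.asarray(series_per_animal[animal], dtype=float)
        n = len(series)
        if len(events) and isinstance(events[0], BoundaryEvent):
            if align not in ("start", "peak", "end"):
                raise ValueError("align must be 'start', 'peak' or 'end'")
            if event_type is not None:
                events = [e for e in events if e.type == event_type]
            anchors = [getattr(e, f"{align}_frame") for e in events]
        else:
            anchors = [int(e) for e in events]
        for j, t0 in enumerate(anchors):
            row = np.full(len(offsets), np.nan)
            pos = t0 + offsets
            ok = (pos >= 0) & (pos < n)
            row[ok] = series[pos[ok]]
            rows.append(row)
            idxs.append(j)
            ids.append(animal)
    if rows:
        values = np.vstack(rows)
    else:
        values = np.empty((0, len(offsets)))
    return AlignedMatrix(values=values, offsets=offsets,
                         event_index=np.asarray(idxs, dtype=int),
                         animal_ids=np.asarray(ids, dtype=object))


def event_triggered_mean(aligned: AlignedMatrix,
                         max_missing_frac: float = 0.1
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Across-event mean at each offset, with a strict missingness rule.

    An offset's mean is reported only when strictly fewer than
    ``max_missing_frac`` of the events are missing at that offset; otherwise
    it is NaN. Returns (mean, n_used) arrays over offsets.
    """
    if aligned.n_events == 0:
        raise ValueError("no events to average")
    missing = np.isnan(aligned.values)
    frac_missing = missing.mean(axis=0)
    n_used = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(missing, np.nan, aligned.values), axis=0)
    mean[frac_missing >= max_missing_frac] = np.nan
    return mean, n_used


def fraction_in_state_before_event(state_bins_per_animal: dict,
                                   event_bins_per_animal: dict,
                                   window_bins: tuple[int, int],
                                   state: int = 0) -> pd.DataFrame:
    """Fraction of events whose animal is in ``state`` at each bin offset.

    ``state_bins_per_animal`` maps animal id -> per-bin decoded state array
    (-1 = missing); ``event_bins_per_animal`` maps animal id -> integer bin
    indices of the events. Missing bins are excluded from the denominator.
    """
    series = {a: np.asarray(s, dtype=float) for a, s in state_bins_per_animal.items()}
    for s in series.values():
        s[s < 0] = np.nan
    aligned = align_to_events(series, event_bins_per_animal, window_bins)
    ok = ~np.isnan(aligned.values)
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(n > 0,
                        (ok & (aligned.values == state)).sum(axis=0) / np.maximum(n, 1),
                        np.nan)
    return pd.DataFrame({"offset_bins": aligned.offsets,
                         "fraction_in_state": frac, "n": n})


def state_at_event(states: np.ndarray, event_bin: int,
                   max_back_bins: int = 6) -> int:
    """Decoded state in effect at an event's bin.

    Events such as lawn leaving censor most of their own bin (the animal is
    off the lawn), so that bin often decodes as missing. The state "at" the
    event is therefore the most recent decoded bin at or before the event
    bin, searched back at most ``max_back_bins``; -1 if none is found.
    """
    states = np.asarray(states)
    b = int(event_bin)
    if b < 0 or b >= len(states):
        return -1
    for k in range(b, max(b - max_back_bins - 1, -1), -1):
        if states[k] >= 0:
            return int(states[k])
    return -1


def state_event_overlap(states: np.ndarray, event_bins: np.ndarray,
                        K: int) -> dict:
    """How decoded states cover the bins that contain events.

    ``states`` is a per-bin decoded state array (-1 = missing); ``event_bins``
    are the bin indices of events. Returns counts per state plus an
    ``unassigned`` bucket for events landing in missing bins, and the
    fraction of assignable events per state.
    """
    states = np.asarray(states)
    counts = {k: 0 for k in range(K)}
    unassigned = 0
    for b in np.asarray(event_bins, dtype=int):
        if b < 0 or b >= len(states) or states[b] < 0:
            unassigned += 1
        else:
            counts[int(states[b])] += 1
    assigned = sum(counts.values())
    frac = {k: (counts[k] / assigned if assigned else np.nan) for k in counts}
    return {"counts": counts, "unassigned": unassigned,
            "n_events": assigned + unassigned, "fraction": frac}


@dataclass
class PreLeavingResult:
    """Paired baseline-vs-final speeds leading into lawn-leaving events."""

    baseline: np.ndarray         # per-event mean speed in the baseline window
    final: np.ndarray            # per-event mean speed in the final window
    diff: np.ndarray             # final - baseline
    t_stat: float
    p_value: float               # one-sided, H1: final > baseline
    n: int

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.final) / np.mean(self.baseline))


def pre_leaving_acceleration(speed_per_animal: dict, events_per_animal: dict,
                             fps: float,
                             baseline_window_s: tuple[float, float] = (-180.0, -60.0),
                             final_window_s: tuple[float, float] = (-30.0, 0.0),
                             min_valid_frac: float = 0.5) -> PreLeavingResult:
    """Test whether animals speed up just before leaving the lawn.

    For each leaving event, the mean speed over ``final_window_s`` (relative
    to the leaving frame) is paired against the mean over
    ``baseline_window_s``; events with less than ``min_valid_frac`` valid
    samples in either window are dropped. A one-sided paired t-test
    (H1: final > baseline) is run on the differences.
    """
    from scipy import stats

    def window(lo_s, hi_s):
        return int(round(lo_s * fps)), int(round(hi_s * fps)) - 1

    base = align_to_events(speed_per_animal, events_per_animal,
                           window(*baseline_window_s), align="start",
                           event_type=EVENT_LEAVING)
    fin = align_to_events(speed_per_animal, events_per_animal,
                          window(*final_window_s), align="start",
                          event_type=EVENT_LEAVING)
    ok_b = (~np.isnan(base.values)).mean(axis=1) >= min_valid_frac
    ok_f = (~np.isnan(fin.values)).mean(axis=1) >= min_valid_frac
    keep = ok_b & ok_f
    if keep.sum() < 2:
        raise ValueError("fewer than 2 usable leaving events")
    b = np.nanmean(base.values[keep], axis=1)
    f = np.nanmean(fin.values[keep], axis=1)
    d = f - b
    t_stat, p_two = stats.ttest_rel(f, b)
    p_one = p_two / 2 if t_stat > 0 else 1 - p_two / 2
    return PreLeavingResult(baseline=b, final=f, diff=d,
                            t_stat=float(t_stat), p_value=float(p_one),
                            n=int(keep.sum()))


@dataclass
class EventSummary:
    """Per-group leaving-event summary."""

    group: str
    n_animals: int
    n_events: int
    events_per_animal_hour: float
    frac_animals_with_event: float
    logit_frac: float


def logit(p: float, n_bins: int) -> float:
    """ln(p / (1 - p)) with p clamped to [eps, 1 - eps], eps = 1/(2 n_bins).

    The clamp keeps proportions of 0 or 1 (possible with finite bin counts)
    finite on the logit scale.
    """
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    eps = 1.0 / (2.0 * n_bins)
    p = min(max(float(p), eps), 1.0 - eps)
    return float(np.log(p / (1.0 - p)))


def leaving_rate_summary(events_per_animal: dict, duration_s_per_animal: dict,
                         group_per_animal: dict | None = None,
                         n_bins_for_logit: int | None = None
                         ) -> list[EventSummary]:
    """Leaving rates per group: events per animal-hour and the fraction of
    animals with at least one leaving event (also on the logit scale)."""
    groups: dict[str, list] = {}
    for animal in events_per_animal:
        g = group_per_animal[animal] if group_per_animal else "all"
        groups.setdefault(g, []).append(animal)
    out = []
    for g, animals in sorted(groups.items()):
        n_events = 0
        n_with = 0
        hours = 0.0
        for a in animals:
            evs = [e for e in events_per_animal[a]
                   if getattr(e, "type", EVENT_LEAVING) == EVENT_LEAVING]
            n_events += len(evs)
            n_with += bool(evs)
            hours += duration_s_per_animal[a] / 3600.0
        frac = n_with / len(animals)
        nb = n_bins_for_logit if n_bins_for_logit is not None else len(animals)
        out.append(EventSummary(
            group=g, n_animals=len(animals), n_events=n_events,
            events_per_animal_hour=n_events / hours if hours else np.nan,
            frac_animals_with_event=frac, logit_frac=logit(frac, nb)))
    return out
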