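"""Event-aligned statistics: what the worm does just before it leaves the lawn.

Simulates a cohort, decodes roam/dwell states, then asks three questions:
do leavings happen out of the roaming state, does the fraction of animals
roaming climb as leaving approaches, and does speed increase in the final
seconds before the exit?
"""
import numpy as np

from wormlawn import (EVENT_LEAVING, decode_hmm, fit_categorical_hmm,
                      fraction_in_state_before_event, label_sequences,
                      leaving_rate_summary, pre_leaving_acceleration,
                      run_study, state_at_event)

results = run_study(60, seed=99)
print(f"{len(results)} animals passed QC")

summary, = leaving_rate_summary(
    {r.animal_id: r.events for r in results},
    {r.animal_id: r.trajectory.duration_s for r in results})
print(f"{summary.n_events} leavings, "
      f"{summary.events_per_animal_hour:.2f} per animal-hour, "
      f"{summary.frac_animals_with_event:.0%} of animals left at least once")

# Decode HMM states, then assign each leaving to the most recent decoded bin
# (the leaving censors most of its own bin).
hmm = fit_categorical_hmm(label_sequences(results), K=2, seed=1)
states, leave_bins = {}, {}
n_roam = n_assigned = 0
for r in results:
    dec = decode_hmm(hmm, r.labels)
    states[r.animal_id] = dec.states
    bins = []
    for e in r.events:
        if e.type != EVENT_LEAVING:
            continue
        b = r.event_bin(e.start_frame)
        if b is None:
            continue
        s = state_at_event(dec.states, b)
        if s < 0:
            continue
        n_assigned += 1
        n_roam += s == 0
        for k in range(b, max(b - 7, -1), -1):
            if dec.states[k] >= 0:
                bins.append(k)
                break
    leave_bins[r.animal_id] = bins
print(f"{n_roam}/{n_assigned} leavings occurred out of decoded roaming bins")

frac = fraction_in_state_before_event(states, leave_bins,
                                      window_bins=(-30, 0), state=0)
for off in (-30, -18, -6, 0):
    row = frac[frac["offset_bins"] == off].iloc[0]
    print(f"  {off * 10 / 60:5.1f} min before leaving: "
          f"{row['fraction_in_state']:.2f} roaming (n={int(row['n'])})")

speeds = {r.animal_id:
          r.frame_features["midbody_speed"].abs().to_numpy(dtype=float)
          for r in results}
events = {r.animal_id: r.events for r in results}
acc = pre_leaving_acceleration(speeds, events, fps=3.0)
print(f"\npre-leaving speed: final 30 s is {acc.mean_ratio:.2f}x the "
      f"baseline window (n={acc.n} events, one-sided p={acc.p_value:.2g})")
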