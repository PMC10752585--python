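# wormlawn

Lawn-centric analysis of single-worm foraging behavior: trajectory tracking
from video, locomotion features, roam/dwell state models, and statistics of
lawn-boundary events (head pokes, leavings, re-entries).

## The science

A *C. elegans* hermaphrodite on a small bacterial lawn alternates between two
long-lived behavioral states: **roaming** — fast, relatively straight runs
that carry it across and occasionally off the lawn — and **dwelling** — slow,
high-turning local search. Decisions at the lawn boundary are discrete and
classifiable: the animal may poke its head past the edge and withdraw
(resuming forward, pausing, or reversing), or commit and leave the lawn
entirely before eventually re-entering. Lawn leaving is rare, strongly
coupled to the roaming state, and preceded by a measurable acceleration in
the final seconds.

`wormlawn` implements that entire analysis chain:

- **synth** — a ground-truthed generator of 40-min, 3 Hz single-animal
  recordings (49-point body splines) with two-state switching dynamics,
  state-coupled leaving hazard, a pre-leaving acceleration motif, scheduled
  head pokes, and tracking dropout; plus a movie renderer.
- **tracking** — movie → trajectory: temporal-median background estimation,
  worm segmentation, constant-velocity Kalman tracking of the centroid,
  skeletonization to a 49-point spline, head/tail assignment from motion,
  and lawn-boundary detection from the background image.
- **features** — frame-level locomotion features (speeds, angular speeds,
  signed midbody speed, head motion relative to the midbody, quirkiness,
  forward/pause/reverse motion state) and 10-s binning with a strict
  missing-data rule.
- **lawn_events** — signed boundary distance, excursion extraction,
  head-poke/leaving/re-entry classification, off-lawn censoring, and
  per-animal quality control.
- **state_models** — the roam/dwell decision line (speed > angular/450), a
  categorical HMM over the noisy line labels, and a K-state autoregressive
  HMM on continuous bin features with EM training, a state-matched Gaussian
  baseline, held-out evaluation, and cross-validated selection of K.
- **event_stats** — event-triggered alignment and means (with a ≥10 %
  missingness mask), fraction-in-state before leaving, state–event overlap,
  pre-leaving acceleration with a paired one-sided test, leaving-rate
  summaries, and the logit transform.

See [docs/methods.md](docs/methods.md) for model details, conventions, and
numerical choices.

## Worked example

```python
from wormlawn import SimulationConfig, analyze_animal, simulate_trajectory

trajectory, lawn, truth = simulate_trajectory(SimulationConfig(seed=7))
res = analyze_animal(trajectory, lawn, ground_truth=truth)
```

Running [examples/01_simulate_and_classify.py](examples/01_simulate_and_classify.py)
(the above plus printing) gives:

```text
simulated 7200 frames (40 min at 3 Hz)
QC passed: True
    5.3 min    head_poke_reversal  peak distance -0.16 mm  frames 946-954
    5.8 min    head_poke_reversal  peak distance -0.17 mm  frames 1038-1046
    6.5 min     head_poke_forward  peak distance -0.19 mm  frames 1165-1175
    9.0 min       head_poke_pause  peak distance -0.23 mm  frames 1624-1659
   ... (46 more boundary events) ...
   38.0 min    head_poke_reversal  peak distance -0.14 mm  frames 6835-6841

240 bins, 240 observed; 7.9% of observed bins roaming
line classifier agrees with generator state in 95% of bins
```

The other narrative scripts in [examples/](examples/) cover tracking a
rendered movie back into a trajectory (`02`), fitting and selecting the state
models (`03`), and the event-aligned statistics of leaving (`04`).

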