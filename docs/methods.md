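# Methods

This document describes the models, conventions and numerical choices behind
`wormlawn`. Units are millimeters, seconds, and degrees unless stated
otherwise; frames index time at a fixed rate (default 3 Hz) and "bins" are
non-overlapping 10-s windows of frames.

## Posture and trajectory representation

A tracked animal is a `Trajectory`: per frame, a 49-point body spline
(head = point 0, tail = point 48), the spline centroid, a visibility flag,
and the capture rate. Invisible frames carry NaN coordinates. Head (spline
points 1–8) and midbody (points 17–33) centroids summarize the anterior and
the most stable part of the body.

## Frame features

All speeds use centered finite differences: the value at frame *t* compares
frames *t* − 1 and *t* + 1, so a single missing frame voids its two
neighbors but not itself, and the first and last frames are always missing.

- **Path / centroid / midbody speed** (mm/s): ‖x(t+1) − x(t−1)‖ · fps / 2.
- **Signed midbody speed**: magnitude as above, sign from the projection of
  the velocity onto the head–tail body axis; negative values are reversals.
- **Angular speed** (deg/s): unsigned heading change of the displacement
  vector; undefined (NaN) when the animal does not displace.
- **Head motion relative to midbody**: polar decomposition of the head
  centroid about the midbody centroid — radial (mm/s) and angular (deg/s)
  velocities, with angle steps wrapped into (−180°, 180°].
- **Motion state**: forward / pause / reverse from the signed midbody speed
  with a pause band of |v| < 0.02 mm/s (exactly at threshold counts as
  moving).
- **Quirkiness**: √(1 − (minor/major)²) of the posture's bounding ellipse;
  1 for a fully elongated animal, 0 for a circular blob.

## Binning

Frames aggregate into 10-s bins (a trailing partial bin is dropped). A bin's
value is the mean over its observed frames, but a bin with more than 50 %
missing frames is itself missing (NaN) and carries a `missing_frac` column.
Conditional quantities (forward-only and reverse-only speeds, fractions of
time forward/paused/reversing) are computed within-bin from the motion
state. The canonical 5-dimensional AR-HMM observation vector per bin is:
fraction of frames moving forward, mean forward midbody speed, midbody
angular speed, and the head's relative angular and radial velocities.

## Lawn-boundary events

The lawn is a polygon (`LawnGeometry`); the signed distance of a point is
positive inside, negative outside, computed from the exact point-to-polygon
distance. Event detection runs on the head centroid's signed distance:

1. **Excursion extraction.** A candidate excursion is a maximal run of
   frames that are outside the lawn or missing, trimmed to its first and
   last *observed*-outside frames. Runs containing or bordering missing
   frames are kept but flagged `interrupted`.
2. **Leaving**: an excursion during which every spline point of the body is
   off the lawn in some observed frame. Its peak is the deepest observed
   frame up to the full-body exit. The matching **re-entry** is the frame
   the head centroid first returns inside.
3. **Head pokes**: excursions that end with the head back on the lawn while
   the body never fully left, deeper than a minimum depth (one pixel,
   default 0.01 mm) to suppress boundary jitter. The poke subtype comes from
   the motion state during the 30 s after the peak, capped at the excursion
   end: a reversal poke if any reversal occurs, otherwise a pause poke if
   any pause occurs, otherwise a forward poke. Interrupted excursions are
   never classified as pokes — a missing frame could hide a full-body exit —
   but remain valid leavings because a leaving is established by observed
   frames alone.

**Off-lawn censoring.** Frames between each leaving and its re-entry (or the
end of the recording for an unresolved leaving) are marked off-lawn; all
state-model inputs are set to NaN there and an `on_lawn` column records the
mask. Lawn-centric behavioral states are undefined off the lawn, so those
frames must not contribute to bins or state models.

## Quality control

Per-animal inclusion rules (1-h assay defaults; shorter recordings scale
pro-rata with a warning):

| rule | reject when | code |
|---|---|---|
| visibility | tracked for less than half the expected duration | `visible_lt_half` |
| lawn contact | on the lawn < 60 s within the first 20 min | `not_on_lawn_1min_in_first_20min` |
| plate bump | the plate-bumped input flag is set | `plate_bumped` |

Regardless of the verdict, `apply_qc` returns the final 40 min of the
recording as the analysis window; all bins, labels and state models are
computed on that window. Event frames index the full recording and convert
to analysis bins via `AnimalResult.event_bin`.

## Roam/dwell decision line

Each 10-s bin is labeled from its centroid speed *v* (mm/s) and centroid
angular speed *a* (deg/s): roaming when *v* > *a* / 450, dwelling otherwise
(ties dwell). Bins with a missing input get no label. The slope of 450
(deg/s per mm/s) separates fast, straight runs from slow, curvy local
search.

## Categorical HMM

A K-state HMM over the noisy per-bin roam/dwell labels, fit by Baum–Welch
(EM). Missing bins split each animal's label sequence into fully observed
segments; each segment restarts from the initial distribution. Decoding
(posterior marginals) runs per segment and leaves missing bins at state −1.
States are sorted so state 0 has the highest emission probability for the
roam symbol.

## AR-HMM

A K-state autoregressive HMM on continuous bin features: given state k,
x_t ~ N(A_k x_{t−1} + b_k, Q_k). The first observation of each sequence is
conditioned on, so the likelihood starts at t = 1. EM alternates
forward–backward over the AR emission densities with per-state weighted
least squares for [A_k | b_k] and weighted residual covariances for Q_k.
States are sorted ascending by the occupancy-weighted mean of a chosen
feature (default: the second, forward midbody speed), making state indices
comparable across fits. Features may optionally be standardized before
fitting; the stored means/scales make the fit self-describing.

The **Gaussian baseline** fits a state-matched mixture-free model: a single
Gaussian per fitted AR state over the same conditional observations
(t ≥ 1), so a held-out comparison isolates the value of the autoregressive
dynamics rather than of extra parameters.

**Model selection** (`select_arhmm_K`): k-fold cross-validation over whole
sequences (folds assigned by a seeded permutation), scoring mean held-out
log-likelihood per observation for each K in the grid; the argmax wins.

## Numerical choices

- **Scaled forward–backward.** The forward pass normalizes α at every step
  and accumulates log-scaling factors, so likelihoods of long sequences
  never underflow; the backward pass reuses the same scalers. The total
  log-likelihood equals exhaustive enumeration over all state paths to
  within 1e-8 relative error (verified for all sequence lengths ≤ 8,
  K ≤ 3, both emission families).
- **EM restarts and initialization.** Fits run several seeded restarts and
  keep the best final log-likelihood; results are deterministic given the
  seed. For the AR-HMM, the first restart initializes state responsibilities
  from k-means on stacked (x_{t−1}, x_t) pairs, the rest from random
  contiguous blocks (block length ≥ 10 bins) so every restart starts from
  temporally coherent segments. Initial responsibilities get only a tiny
  additive smoothing (1e-3): larger smoothing lets high-leverage
  observations from other states' operating regions dominate the first
  weighted least-squares step and collapse all states onto one dynamics
  matrix.
- **Monotonicity.** The per-iteration log-likelihood history is stored on
  every fit and is non-decreasing up to 1e-6; tests assert this.

## Event-aligned statistics

- `align_to_events` cuts fixed windows of bins around each event (anchored
  at the event's start, peak, or end); windows run off the edge of a
  recording as NaN.
- `event_triggered_mean` averages across events at each offset but masks
  any offset where ≥ 10 % of events are missing, so edge effects cannot
  silently bias the trace. It reports the per-offset event count.
- **State at an event.** A leaving censors most of its own bin (the animal
  goes off-lawn), so the bin usually decodes as missing. The state "at" an
  event is therefore the most recent decoded bin, looking back at most
  6 bins (1 min); events with no decoded bin in reach are unassigned.
- `pre_leaving_acceleration` compares, per leaving, the mean speed in a
  final window (−30–0 s) against a baseline window (−180–−60 s), requiring
  half of each window observed, and runs a one-sided paired t-test
  (H1: final > baseline).
- `leaving_rate_summary` reports events per animal-hour and the fraction of
  animals with ≥ 1 event per group; `logit` uses a clamped transform with
  ε = 1/(2n) so 0 and 1 stay finite.

## Synthetic generator

`simulate_trajectory` produces ground-truthed recordings for testing and
calibration. It is a two-state semi-Markov walker with scripted boundary
motifs, not a biomechanical model; its scope is to exercise every pipeline
stage with known answers. Key defaults (`SimulationConfig`):

| parameter | default | units |
|---|---|---|
| `duration_s` / `fps` | 2400 / 3 | s, Hz |
| `lawn_radius` | 1.5 | mm |
| `roam_speed_mean` / `dwell_speed_mean` | 0.15 / 0.03 | mm/s |
| `roam_turn_rate` / `dwell_turn_rate` | 30 / 120 | deg/s |
| `p_stay_roam` / `p_stay_dwell` | 0.80 / 0.97 | per 10-s bin |
| `leave_hazard_roam` / `leave_hazard_dwell` | 0.008 / 0.0002 | per 10-s bin |
| `headpoke_rate` | 2.0 | events/min |
| `poke_type_probs` (fwd, pause, rev) | 0.25, 0.20, 0.55 | — |
| `off_lawn_dwell_s` | 60 | s |
| `missing_frac` | 0.02 | — |
| `reversal_rate_roam_per_min` / `dwell` | 0.3 / 4.0 | events/min |
| `worm_length` / `worm_width` | 1.0 / 0.08 | mm |
| `pixel_scale` | 0.01 | mm/px |

Leavings are preceded by a speed-up motif (`accel_motif`) so event-aligned
statistics have a known positive effect to detect. The generator returns a
`GroundTruth` record (per-bin and per-frame states, scheduled events) for
scoring.

`render_movie` rasterizes the worm as a dark tube (intensity 60) over a
faint lawn disk (180) on flat agar (200); `track_movie` inverts it with
temporal-median background estimation, threshold segmentation, a
constant-velocity Kalman filter over centroids (with gated updates and
bounded coasting through missing detections), morphological
skeletonization, and head/tail assignment from sustained motion direction
(the head leads net displacement; ambiguous, low-motion movies are flagged).

## Limitations

- The generator's kinematics are schematic: no biomechanical undulation
  model, constant body length, circular lawns only in the bundled configs
  (arbitrary polygons are supported by the analysis).
- Head pokes interrupted by tracking dropouts are conservatively discarded
  rather than imputed; heavy dropout near the boundary will undercount
  pokes.
- The AR-HMM assumes linear per-state dynamics with Gaussian noise on 10-s
  bins; sub-bin structure (individual reversals) is only visible through
  the bin-level fractions.
- Cross-validated K selection compares predictive likelihood, not
  identifiability; with few or short sequences the curve can be flat across
  adjacent K.
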