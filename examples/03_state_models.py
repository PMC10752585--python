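"""Fit the roam/dwell state models to a small simulated cohort.

Three layers, in increasing order of structure:

1. the decision line: a bin is "roaming" when its centroid speed (mm/s)
   exceeds its angular speed (deg/s) divided by 450;
2. a 2-state categorical HMM over those noisy per-bin labels, which smooths
   them through the known persistence of behavioral states;
3. an autoregressive HMM directly on continuous bin features, with a
   state-matched Gaussian baseline and cross-validated selection of the
   number of states.
"""
import numpy as np

from wormlawn import (STATE_ROAM, decode_hmm, feature_sequences, fit_arhmm,
                      fit_categorical_hmm, fit_gaussian_baseline, heldout_eval,
                      label_sequences, run_study, select_arhmm_K)

results = run_study(20, seed=123)
print(f"{len(results)} animals passed QC")

# --- categorical HMM over decision-line labels ------------------------------
hmm = fit_categorical_hmm(label_sequences(results), K=2, seed=1)
print("\ncategorical HMM (state 0 = roam):")
print(f"  self-transition roam  {hmm.transitions[0, 0]:.3f}")
print(f"  self-transition dwell {hmm.transitions[1, 1]:.3f}")
print(f"  emission fidelity     {hmm.emissions[0, 0]:.3f} / "
      f"{hmm.emissions[1, 1]:.3f}")

dec = decode_hmm(hmm, results[0].labels)
raw = np.asarray(results[0].labels, dtype=object)
flipped = sum(1 for s, lab in zip(dec.states, raw)
              if s >= 0 and lab is not None
              and (s == 0) != (lab == STATE_ROAM))
print(f"  decoding animal 0 relabeled {flipped} of {len(raw)} bins")

# --- AR-HMM vs Gaussian baseline on held-out animals -------------------------
train = feature_sequences(results[:14])
test = feature_sequences(results[14:])
arhmm = fit_arhmm(train, K=2, seed=2, n_restarts=3)
base = fit_gaussian_baseline(train, match=arhmm)
he = heldout_eval(arhmm, base, test)
print("\nheld-out log-likelihood per observation:")
print(f"  AR-HMM    {he.ll_arhmm / he.n_obs:8.3f}")
print(f"  Gaussian  {he.ll_gaussian / he.n_obs:8.3f}")

# --- how many states? --------------------------------------------------------
best, table = select_arhmm_K(feature_sequences(results), K_grid=(1, 2, 3),
                             folds=3, seed=3, n_restarts=2)
print(f"\ncross-validated state count: K = {best}")
print(table.to_string(index=False))
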