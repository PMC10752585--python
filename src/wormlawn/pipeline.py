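"""End-to-end per-animal analysis and multi-animal study helpers.

``analyze_animal`` runs the full single-animal pipeline: frame features,
boundary events, off-lawn censoring, QC and truncation to the analysis
window, 10-s binning, and line-classifier roam/dwell labels.

``run_study`` simulates and analyzes a cohort of synthetic animals with
independent seeds derived from one study seed.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import GroundTruth, LawnGeometry, QCReport, Trajectory
from .features import ARHMM_FEATURES, bin_features, compute_frame_features
from .lawn_events import apply_qc, censor_off_lawn, detect_events, off_lawn_frames
from .state_models import classify_roam_dwell_line
from .synth import SimulationConfig, simulate_trajectory

__all__ = ["AnimalResult", "analyze_animal", "run_study", "derive_seeds",
           "label_sequences", "feature_sequences"]


@dataclass
class AnimalResult:
    """Everything the pipeline produced for one animal.

    Event frames index the *full* recording; ``tail_start`` is the frame at
    which the truncated analysis window begins, so an event at full-recording
    frame f sits at analysis frame f - tail_start (when >= 0) and in analysis
    bin (f - tail_start) // bin_frames.
    """

    trajectory: Trajectory              # full recording
    geometry: LawnGeometry
    qc: QCReport
    events: list                        # BoundaryEvent, full-recording frames
    frame_features: pd.DataFrame        # censored, full recording, on_lawn col
    analysis: Trajectory                # truncated analysis window
    tail_start: int
    binned: pd.DataFrame                # bins over the analysis window
    labels: np.ndarray                  # per-bin roam/dwell (None = missing)
    ground_truth: GroundTruth | None = None

    @property
    def animal_id(self) -> str:
        return self.trajectory.animal_id

    @property
    def bin_frames(self) -> int:
        return int(round(10.0 * self.trajectory.fps))

    def event_bin(self, frame: int) -> int | None:
        """Analysis-window bin index of a full-recording frame, or None."""
        f = frame - self.tail_start
        if f < 0:
            return None
        b = f // self.bin_frames
        return int(b) if b < len(self.binned) else None


def analyze_animal(trajectory: Trajectory, geometry: LawnGeometry,
                   bumped: bool = False,
                   expected_duration_s: float | None = None,
                   analysis_tail_s: float = 2400.0,
                   bin_s: float = 10.0,
                   ground_truth: GroundTruth | None = None) -> AnimalResult:
    """Single-animal pipeline from oriented trajectory + lawn polygon.

    ``expected_duration_s`` defaults to the recording's own duration (no
    pro-rata warning); pass 3600 for a standard 1-h assay.
    """
    if expected_duration_s is None:
        expected_duration_s = trajectory.duration_s
    ff = compute_frame_features(trajectory)
    events = detect_events(trajectory, geometry, ff)
    off = off_lawn_frames(events, trajectory.n_frames)
    ff = censor_off_lawn(ff, off)
    qc, analysis = apply_qc(trajectory, ff["on_lawn"].to_numpy(),
                            bumped=bumped,
                            expected_duration_s=expected_duration_s,
                            analysis_tail_s=analysis_tail_s)
    tail_start = trajectory.n_frames - analysis.n_frames
    ff_tail = ff.iloc[tail_start:].reset_index(drop=True)
    binned = bin_features(ff_tail, trajectory.fps, bin_s=bin_s,
                          on_lawn=ff_tail["on_lawn"].to_numpy())
    labels = classify_roam_dwell_line(
        binned["centroid_speed"].to_numpy(),
        binned["centroid_angular_speed"].to_numpy())
    return AnimalResult(trajectory=trajectory, geometry=geometry, qc=qc,
                        events=events, frame_features=ff, analysis=analysis,
                        tail_start=tail_start, binned=binned, labels=labels,
                        ground_truth=ground_truth)


def derive_seeds(seed: int, n: int) -> np.ndarray:
    """n independent 31-bit child seeds from one study seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def run_study(n_animals: int, seed: int,
              config: SimulationConfig | None = None,
              keep_failed_qc: bool = False) -> list[AnimalResult]:
    """Simulate and analyze a cohort of synthetic animals.

    Each animal gets an independent seed derived from ``seed``; the base
    ``config`` supplies every other parameter. Animals failing QC are dropped
    unless ``keep_failed_qc``.
    """
    base = config if config is not None else SimulationConfig()
    out = []
    for i, s in enumerate(derive_seeds(seed, n_animals)):
        cfg = replace(base, seed=int(s))
        traj, lawn, truth = simulate_trajectory(cfg)
        traj.animal_id = f"sim-{seed}-{i:03d}"
        res = analyze_animal(traj, lawn, bin_s=base.bin_s,
                             ground_truth=truth)
        if res.qc.passed or keep_failed_qc:
            out.append(res)
    return out


def label_sequences(results: list[AnimalResult]) -> list[np.ndarray]:
    """Contiguous non-missing roam/dwell label runs pooled over animals."""
    from .state_models import split_on_missing

    seqs = []
    for r in results:
        seqs.extend(s for s in split_on_missing(r.labels) if len(s) >= 2)
    return seqs


def feature_sequences(results: list[AnimalResult],
                      features: tuple = ARHMM_FEATURES) -> list[np.ndarray]:
    """Contiguous fully observed feature-vector runs pooled over animals."""
    seqs = []
    for r in results:
        X = r.binned[list(features)].to_numpy(dtype=float)
        ok = np.isfinite(X).all(axis=1)
        t = 0
        while t < len(X):
            if not ok[t]:
                t += 1
                continue
            start = t
            while t < len(X) and ok[t]:
                t += 1
            if t - start >= 2:
                seqs.append(X[start:t])
    return seqs
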