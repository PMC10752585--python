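"""File formats: trajectory CSV, lawn JSON, event CSV, TIFF stacks, model JSON.

All tabular formats are plain CSV readable by pandas; geometry and model
parameters are JSON. Movie stacks use TIFF via tifffile.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import N_SPLINE, BoundaryEvent, LawnGeometry, Trajectory
from .state_models import ARHMMParams, CategoricalHMMParams

__all__ = [
    "save_trajectory_csv", "load_trajectory_csv",
    "save_lawn_json", "load_lawn_json",
    "save_events_csv", "load_events_csv",
    "save_movie_tiff", "load_movie_tiff",
    "save_binned_csv", "load_binned_csv",
    "save_model_json", "load_model_json",
]


def save_trajectory_csv(trajectory: Trajectory, path: str | Path) -> None:
    """One row per frame: frame, time_s, visible, x_1..x_49, y_1..y_49, cx, cy.

    fps, pixel scale and flags travel in '#key=value' header comment lines.
    """
    cols: dict = {
        "frame": np.arange(trajectory.n_frames),
        "time_s": trajectory.time_s,
        "visible": trajectory.visible.astype(int),
    }
    for i in range(N_SPLINE):
        cols[f"x_{i + 1}"] = trajectory.spline[:, i, 0]
    for i in range(N_SPLINE):
        cols[f"y_{i + 1}"] = trajectory.spline[:, i, 1]
    cols["cx"] = trajectory.centroid[:, 0]
    cols["cy"] = trajectory.centroid[:, 1]
    header = (
        f"#fps={trajectory.fps}\n"
        f"#pixel_scale={trajectory.pixel_scale if trajectory.pixel_scale is not None else ''}\n"
        f"#animal_id={trajectory.animal_id}\n"
        f"#oriented={int(trajectory.oriented)}\n"
        f"#orientation_ambiguous={int(trajectory.orientation_ambiguous)}\n"
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(header)
        pd.DataFrame(cols).to_csv(fh, index=False)


def load_trajectory_csv(path: str | Path) -> Trajectory:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            k, v = line[1:].strip().split("=", 1)
            meta[k] = v
        df = pd.read_csv(fh)
    T = len(df)
    spline = np.empty((T, N_SPLINE, 2))
    for i in range(N_SPLINE):
        spline[:, i, 0] = df[f"x_{i + 1}"]
        spline[:, i, 1] = df[f"y_{i + 1}"]
    return Trajectory(
        fps=float(meta["fps"]),
        time_s=df["time_s"].to_numpy(),
        visible=df["visible"].to_numpy(dtype=bool),
        spline=spline,
        centroid=df[["cx", "cy"]].to_numpy(),
        pixel_scale=float(meta["pixel_scale"]) if meta.get("pixel_scale") else None,
        animal_id=meta.get("animal_id", "worm"),
        oriented=bool(int(meta.get("oriented", 1))),
        orientation_ambiguous=bool(int(meta.get("orientation_ambiguous", 0))),
    )


def save_lawn_json(geometry: LawnGeometry, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "provenance": geometry.provenance,
        "vertices": geometry.vertices.tolist(),
    }, indent=2))


def load_lawn_json(path: str | Path) -> LawnGeometry:
    d = json.loads(Path(path).read_text())
    return LawnGeometry(vertices=np.asarray(d["vertices"], dtype=float),
                        provenance=d.get("provenance", "provided"))


def save_events_csv(events: list[BoundaryEvent], path: str | Path,
                    animal_id: str | None = None) -> None:
    rows = [{
        "animal_id": animal_id or "",
        "type": e.type,
        "start_frame": e.start_frame,
        "peak_frame": e.peak_frame,
        "end_frame": e.end_frame,
        "peak_distance_mm": e.peak_distance_mm,
    } for e in events]
    pd.DataFrame(rows, columns=["animal_id", "type", "start_frame",
                                "peak_frame", "end_frame",
                                "peak_distance_mm"]).to_csv(path, index=False)


def load_events_csv(path: str | Path) -> list[BoundaryEvent]:
    df = pd.read_csv(path)
    return [BoundaryEvent(type=r.type, start_frame=int(r.start_frame),
                          peak_frame=int(r.peak_frame),
                          end_frame=int(r.end_frame),
                          peak_distance_mm=float(r.peak_distance_mm))
            for r in df.itertuples()]


def save_movie_tiff(stack: np.ndarray, path: str | Path) -> None:
    import tifffile
    tifffile.imwrite(str(path), np.asarray(stack))


def load_movie_tiff(path: str | Path) -> np.ndarray:
    import tifffile
    return tifffile.imread(str(path))


def save_binned_csv(binned: pd.DataFrame, path: str | Path) -> None:
    binned.to_csv(path, index=False)


def load_binned_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _arr(x):
    return None if x is None else np.asarray(x, dtype=float)


def save_model_json(params: CategoricalHMMParams | ARHMMParams,
                    path: str | Path) -> None:
    """Serialize fitted HMM / AR-HMM parameters to JSON (round-trippable)."""
    if isinstance(params, CategoricalHMMParams):
        d = {
            "model": "categorical_hmm",
            "initial": params.initial.tolist(),
            "transitions": params.transitions.tolist(),
            "emissions": params.emissions.tolist(),
            "alphabet": list(params.alphabet),
            "log_likelihood": params.log_likelihood,
        }
    elif isinstance(params, ARHMMParams):
        d = {
            "model": "arhmm",
            "initial": params.initial.tolist(),
            "transitions": params.transitions.tolist(),
            "A": params.A.tolist(),
            "b": params.b.tolist(),
            "Q": params.Q.tolist(),
            "feature_names": list(params.feature_names),
            "feature_mean": None if params.feature_mean is None
            else params.feature_mean.tolist(),
            "feature_std": None if params.feature_std is None
            else params.feature_std.tolist(),
            "log_likelihood": params.log_likelihood,
        }
    else:
        raise TypeError(f"cannot serialize {type(params).__name__}")
    Path(path).write_text(json.dumps(d, indent=2))


def load_model_json(path: str | Path) -> CategoricalHMMParams | ARHMMParams:
    d = json.loads(Path(path).read_text())
    if d["model"] == "categorical_hmm":
        return CategoricalHMMParams(
            initial=np.asarray(d["initial"]),
            transitions=np.asarray(d["transitions"]),
            emissions=np.asarray(d["emissions"]),
            alphabet=tuple(d["alphabet"]),
            log_likelihood=d.get("log_likelihood", float("nan")))
    if d["model"] == "arhmm":
        return ARHMMParams(
            initial=np.asarray(d["initial"]),
            transitions=np.asarray(d["transitions"]),
            A=np.asarray(d["A"]), b=np.asarray(d["b"]), Q=np.asarray(d["Q"]),
            feature_names=tuple(d.get("feature_names", ())),
            feature_mean=_arr(d.get("feature_mean")),
            feature_std=_arr(d.get("feature_std")),
            log_likelihood=d.get("log_likelihood", float("nan")))
    raise ValueError(f"unknown model type {d['model']!r}")
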