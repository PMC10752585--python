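"""Core data containers shared by every stage of the pipeline.

Units are millimetres and seconds throughout; image rendering converts to
pixels via a ``pixel_scale`` (mm/pixel). Frames are 0-based.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import shapely

#: number of points in a body spline
N_SPLINE = 49
#: head = spline points 1-8 (1-based), midbody = points 17-33
HEAD_SLICE = slice(0, 8)
MIDBODY_SLICE = slice(16, 33)

STATE_ROAM = "roam"
STATE_DWELL = "dwell"

EVENT_LEAVING = "leaving"
EVENT_REENTRY = "reentry"
EVENT_HEAD_POKE_FORWARD = "head_poke_forward"
EVENT_HEAD_POKE_PAUSE = "head_poke_pause"
EVENT_HEAD_POKE_REVERSAL = "head_poke_reversal"
EVENT_TYPES = (
    EVENT_LEAVING,
    EVENT_REENTRY,
    EVENT_HEAD_POKE_FORWARD,
    EVENT_HEAD_POKE_PAUSE,
    EVENT_HEAD_POKE_REVERSAL,
)
HEAD_POKE_TYPES = (
    EVENT_HEAD_POKE_FORWARD,
    EVENT_HEAD_POKE_PAUSE,
    EVENT_HEAD_POKE_REVERSAL,
)


@dataclass
class Trajectory:
    """A single animal's tracked posture over time.

    ``spline`` holds 49 ordered (x, y) points per frame in mm; after head/tail
    assignment point index 0 is the head end in every frame. Invisible frames
    carry NaN coordinates.
    """

    fps: float
    time_s: np.ndarray          # (T,)
    visible: np.ndarray         # (T,) bool
    spline: np.ndarray          # (T, 49, 2) mm, NaN when invisible
    centroid: np.ndarray        # (T, 2) mm
    pixel_scale: float | None = None
    animal_id: str = "worm"
    oriented: bool = True
    orientation_ambiguous: bool = False

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        self.spline = np.asarray(self.spline, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.spline.ndim != 3 or self.spline.shape[1:] != (N_SPLINE, 2):
            raise ValueError(
                f"spline must have shape (T, {N_SPLINE}, 2), got {self.spline.shape}"
            )
        if not (len(self.time_s) == len(self.visible) == len(self.spline) == len(self.centroid)):
            raise ValueError("per-frame arrays must share a common length")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def head(self) -> np.ndarray:
        """Head centroid (mean of spline points 1-8) per frame, shape (T, 2)."""
        return self.spline[:, HEAD_SLICE].mean(axis=1)

    def midbody(self) -> np.ndarray:
        """Midbody centroid (mean of spline points 17-33) per frame, shape (T, 2)."""
        return self.spline[:, MIDBODY_SLICE].mean(axis=1)

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        return Trajectory(
            fps=self.fps,
            time_s=self.time_s[start:stop],
            visible=self.visible[start:stop],
            spline=self.spline[start:stop],
            centroid=self.centroid[start:stop],
            pixel_scale=self.pixel_scale,
            animal_id=self.animal_id,
            oriented=self.oriented,
            orientation_ambiguous=self.orientation_ambiguous,
        )


@dataclass
class LawnGeometry:
    """Closed polygon outlining the bacterial lawn, in trajectory coordinates."""

    vertices: np.ndarray        # (N, 2) mm, implicitly closed
    provenance: str = "provided"  # "detected" | "provided"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3 or self.vertices.shape[1] != 2:
            raise ValueError("lawn polygon needs >= 3 (x, y) vertices")

    @cached_property
    def polygon(self) -> shapely.Polygon:
        poly = shapely.Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("lawn polygon is not a simple (non-self-intersecting) polygon")
        return poly

    @classmethod
    def disk(cls, center: tuple[float, float], radius: float, n_vertices: int = 64,
             provenance: str = "provided") -> "LawnGeometry":
        if radius <= 0:
            raise ValueError("lawn_radius must be positive")
        ang = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
        verts = np.column_stack([
            center[0] + radius * np.cos(ang),
            center[1] + radius * np.sin(ang),
        ])
        return cls(vertices=verts, provenance=provenance)


@dataclass(frozen=True)
class BoundaryEvent:
    """One classified lawn-boundary interaction."""

    type: str
    start_frame: int
    peak_frame: int
    end_frame: int
    peak_distance_mm: float

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if not (self.start_frame <= self.peak_frame <= self.end_frame):
            raise ValueError("event frames must satisfy start <= peak <= end")


@dataclass
class GroundTruth:
    """What the synthetic generator knows about an animal it produced."""

    state_per_bin: np.ndarray            # (n_bins,) of "roam"/"dwell"
    events: list[BoundaryEvent]
    accel_onsets: np.ndarray             # frame indices of acceleration-motif onsets
    commanded_speed: np.ndarray          # (T,) signed path speed in mm/s
    state_per_frame: np.ndarray          # (T,) of "roam"/"dwell"


@dataclass
class QCReport:
    """Per-animal inclusion decision with the identifiers of failed rules."""

    animal_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be True exactly when reasons is empty")
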