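"""Render a movie of a simulated worm, track it back, and score the tracker.

``render_movie`` draws the worm as a dark tube on a faint lawn disk over flat
agar, at a configurable pixel scale.  ``track_movie`` recovers a trajectory
from the pixels alone: background subtraction, worm segmentation, a
constant-velocity Kalman filter over centroids, skeletonization, and
head/tail assignment from sustained motion direction.
"""
import numpy as np

from wormlawn import (SimulationConfig, detect_lawn_boundary,
                      estimate_background, render_movie, simulate_trajectory,
                      track_movie)

# A mostly-roaming animal so there is plenty of motion to track.
cfg = SimulationConfig(seed=5, duration_s=120.0, missing_frac=0.0,
                       p_stay_roam=0.999, p_stay_dwell=0.05, lawn_radius=4.0,
                       headpoke_rate=0.0, leave_hazard_roam=0.0,
                       leave_hazard_dwell=0.0,
                       reversal_rate_roam_per_min=0.0,
                       reversal_rate_dwell_per_min=0.0)
traj, lawn, _ = simulate_trajectory(cfg)
movie = render_movie(traj, lawn, pixel_scale=cfg.pixel_scale)
print(f"rendered {movie.stack.shape[0]} frames of "
      f"{movie.stack.shape[1]}x{movie.stack.shape[2]} px "
      f"at {cfg.pixel_scale * 1000:.0f} um/px")

# The temporal-median background contains no worm, so the lawn boundary can
# be read straight off it.
bg = estimate_background(movie.stack)
det = detect_lawn_boundary(bg, pixel_scale=cfg.pixel_scale,
                           origin_mm=movie.origin_mm)
import shapely
print(f"detected lawn area {shapely.area(det.polygon):.1f} mm^2 "
      f"(true {np.pi * cfg.lawn_radius ** 2:.1f} mm^2)")

tracked = track_movie(movie.stack, fps=traj.fps, pixel_scale=cfg.pixel_scale,
                      origin_mm=movie.origin_mm)

ok = tracked.visible & traj.visible
err_px = np.linalg.norm(tracked.centroid[ok] - traj.centroid[ok],
                        axis=1) / cfg.pixel_scale
head_err = np.linalg.norm(tracked.spline[ok, 0] - traj.spline[ok, 0], axis=1)
tail_err = np.linalg.norm(tracked.spline[ok, 0] - traj.spline[ok, -1], axis=1)
print(f"centroid RMS error: {np.sqrt(np.mean(err_px ** 2)):.2f} px")
print(f"head assigned to the correct end in "
      f"{np.mean(head_err < tail_err):.1%} of frames")
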