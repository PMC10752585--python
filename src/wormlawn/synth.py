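"""Synthetic single-worm foraging recordings.

The generator emulates 40-min, 3 frames-per-second recordings of one animal
on a small circular bacterial lawn: two-state (roam/dwell) switching per 10-s
bin, a lawn-leaving hazard coupled to the behavioral state, a linear speed
ramp in the ~30 s before each leaving, head-poke excursions at the lawn
boundary (forward / pause / reversal subtypes), spontaneous reversal bursts,
and missing-completely-at-random invisible frames.

Locomotion model: the head tip performs a correlated random walk (per-frame
heading noise, per-state speed with lognormal frame-to-frame variation); the
49-point body spline trails along the head's path at fixed arc-length
spacing, with a small lateral head swing superimposed on the first ~12
points. Reversals retrace the stored path; when a reversal ends, the path
ahead of the head is discarded and locomotion continues in a fresh
direction.

Commanded per-state speeds are internally calibrated so that the binned
midbody speed measured by the feature extractor is unbiased for the
configured means (path curvature otherwise compresses centroid displacement
by a few percent).
"""
from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import shapely

from .core import (
    EVENT_HEAD_POKE_FORWARD,
    EVENT_HEAD_POKE_PAUSE,
    EVENT_HEAD_POKE_REVERSAL,
    EVENT_LEAVING,
    EVENT_REENTRY,
    HEAD_SLICE,
    N_SPLINE,
    STATE_DWELL,
    STATE_ROAM,
    BoundaryEvent,
    GroundTruth,
    LawnGeometry,
    Trajectory,
)

__all__ = [
    "AccelMotif",
    "SimulationConfig",
    "simulate_state_sequence",
    "simulate_trajectory",
    "render_movie",
    "RenderedMovie",
    "rigid_worm_trajectory",
]


@dataclass(frozen=True)
class AccelMotif:
    """Linear speed ramp ending at the leaving frame."""

    duration_s: float = 30.0
    multiplier: float = 1.5


@dataclass(frozen=True)
class SimulationConfig:
    duration_s: float = 2400.0
    fps: float = 3.0
    lawn_radius: float = 1.5              # mm
    lawn_center: tuple[float, float] = (0.0, 0.0)
    pixel_scale: float = 0.01             # mm / pixel, used only for rendering
    roam_speed_mean: float = 0.15         # mm/s
    dwell_speed_mean: float = 0.03        # mm/s
    roam_turn_rate: float = 30.0          # deg/s, std of heading change
    dwell_turn_rate: float = 120.0        # deg/s (curvature-capped, see notes)
    p_stay_roam: float = 0.80             # per-10-s-bin self-transition
    p_stay_dwell: float = 0.97
    leave_hazard_roam: float = 0.008      # probability per 10-s bin
    leave_hazard_dwell: float = 0.0002
    accel_motif: AccelMotif = field(default_factory=AccelMotif)
    headpoke_rate: float = 2.0            # scheduled events / min
    poke_type_probs: tuple[float, float, float] = (0.25, 0.20, 0.55)  # fwd, pause, rev
    off_lawn_dwell_s: float = 60.0        # mean seconds off lawn before re-entry
    missing_frac: float = 0.02
    reversal_rate_roam_per_min: float = 0.3
    reversal_rate_dwell_per_min: float = 4.0
    reversal_mean_s: float = 1.0
    worm_length: float = 1.0              # mm
    worm_width: float = 0.08              # mm (rendering)
    head_swing_amp: float = 0.035         # mm lateral oscillation of the head tip
    head_swing_period_s: float = 2.0
    speed_cv: float = 0.35                # lognormal sigma of frame speed noise
    bin_s: float = 10.0
    light_bins: tuple[int, ...] | None = None  # optional optogenetic covariate
    light_leave_multiplier: float = 1.0   # hazard multiplier in light bins
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_stay_roam", "p_stay_dwell", "leave_hazard_roam",
                     "leave_hazard_dwell", "missing_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.missing_frac >= 1.0:
            raise ValueError("missing_frac must be < 1")
        if self.lawn_radius <= 0:
            raise ValueError("lawn_radius must be positive")
        if not self.roam_speed_mean > self.dwell_speed_mean:
            raise ValueError("roam_speed_mean must exceed dwell_speed_mean")
        if not self.dwell_turn_rate > self.roam_turn_rate:
            raise ValueError("dwell_turn_rate must exceed roam_turn_rate")
        n = self.duration_s * self.fps
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("fps * duration_s must be a positive integer frame count")
        if self.accel_motif.multiplier <= 1.0:
            raise ValueError("accel_motif.multiplier must be > 1")
        if self.accel_motif.duration_s <= 0 or \
                self.accel_motif.duration_s >= min(self.duration_s, 120.0):
            raise ValueError(
                "accel_motif.duration_s must be positive and shorter than the "
                "pre-leaving alignment window")
        if self.lawn_radius <= self.worm_length / 2:
            raise ValueError("lawn_radius must exceed half the worm length")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def bin_frames(self) -> int:
        return int(round(self.bin_s * self.fps))

    @property
    def n_bins(self) -> int:
        return self.n_frames // self.bin_frames


def _markov_states(p_stay_roam: float, p_stay_dwell: float, n_bins: int,
                   rng: np.random.Generator, start: str | None) -> np.ndarray:
    qr, qd = 1.0 - p_stay_roam, 1.0 - p_stay_dwell
    if start is None:
        p_roam = 0.5 if qr + qd == 0 else qd / (qr + qd)
        cur = STATE_ROAM if rng.random() < p_roam else STATE_DWELL
    else:
        cur = start
    u = rng.random(n_bins)
    out = np.empty(n_bins, dtype=object)
    for i in range(n_bins):
        out[i] = cur
        stay = p_stay_roam if cur == STATE_ROAM else p_stay_dwell
        if u[i] >= stay:
            cur = STATE_DWELL if cur == STATE_ROAM else STATE_ROAM
    return out.astype(str)


def simulate_state_sequence(p_stay_roam: float, p_stay_dwell: float, n_bins: int,
                            seed: int, start: str | None = None) -> np.ndarray:
    """Two-state Markov chain of per-bin roam/dwell labels.

    ``start`` fixes the first label; by default it is drawn from the chain's
    stationary distribution.
    """
    for name, v in (("p_stay_roam", p_stay_roam), ("p_stay_dwell", p_stay_dwell)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    return _markov_states(p_stay_roam, p_stay_dwell, n_bins,
                          np.random.default_rng(seed), start)


# ---------------------------------------------------------------------------
# path machinery


class _Path:
    """Append-only polyline with arc-length addressing and truncation."""

    def __init__(self, x0: float, y0: float, heading: float):
        self.px = [x0]
        self.py = [y0]
        self.ps = [0.0]
        self.heading = heading

    @property
    def end_s(self) -> float:
        return self.ps[-1]

    def extend(self, ds: float, dtheta: float) -> None:
        self.heading += dtheta
        if ds <= 1e-9:
            return
        self.px.append(self.px[-1] + math.cos(self.heading) * ds)
        self.py.append(self.py[-1] + math.sin(self.heading) * ds)
        self.ps.append(self.ps[-1] + ds)

    def pos_at(self, s: float) -> tuple[float, float]:
        ps = self.ps
        if s >= ps[-1]:
            return self.px[-1], self.py[-1]
        if s <= 0.0:
            return self.px[0], self.py[0]
        i = bisect_right(ps, s)
        f = (s - ps[i - 1]) / (ps[i] - ps[i - 1])
        return (self.px[i - 1] + f * (self.px[i] - self.px[i - 1]),
                self.py[i - 1] + f * (self.py[i] - self.py[i - 1]))

    def truncate(self, s: float) -> None:
        """Drop the path beyond arc-length ``s`` (the stale segment ahead)."""
        x, y = self.pos_at(s)
        i = bisect_right(self.ps, s)
        del self.px[i:], self.py[i:], self.ps[i:]
        if not self.ps or self.ps[-1] < s - 1e-12:
            self.px.append(x)
            self.py.append(y)
            self.ps.append(s)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.asarray(self.px), np.asarray(self.py), np.asarray(self.ps)


def _ang_diff(target: float, current: float) -> float:
    return (target - current + math.pi) % (2 * math.pi) - math.pi


@lru_cache(maxsize=32)
def _speed_scale(v_nominal: float, turn_sd_rad: float, speed_cv: float,
                 fps: float, worm_length: float) -> float:
    """Calibration factor so measured binned midbody speed matches ``v_nominal``.

    Simulates the base correlated random walk for a few thousand frames with a
    fixed internal seed, measures centered-difference midbody-centroid speed,
    and returns target/measured. Cached per kinematic regime.
    """
    rng = np.random.default_rng(123456789)
    n = 4000
    delta = worm_length / (N_SPLINE - 1)
    ds = v_nominal / fps * rng.lognormal(-speed_cv ** 2 / 2, speed_cv, n)
    dth = rng.normal(0.0, turn_sd_rad, n)
    heading = np.cumsum(dth)
    x = np.concatenate([[0.0], np.cumsum(np.cos(heading) * ds)])
    y = np.concatenate([[0.0], np.cumsum(np.sin(heading) * ds)])
    s = np.concatenate([[0.0], np.cumsum(ds)])
    # midbody = mean of spline points 17-33 trailing the head
    k = np.arange(16, 33)
    valid = s > (k[-1] * delta)
    arcs = (s[valid][:, None] - k[None, :] * delta).ravel()
    mx = np.interp(arcs, s, x).reshape(-1, 17).mean(axis=1)
    my = np.interp(arcs, s, y).reshape(-1, 17).mean(axis=1)
    disp = np.hypot(mx[2:] - mx[:-2], my[2:] - my[:-2]) * fps / 2.0
    return v_nominal / float(disp.mean())


def _effective_turn_sd(cfg: SimulationConfig, state: str) -> float:
    """Per-frame heading-noise std in radians, capped by a curvature limit.

    The cap (~380 deg/mm of path) keeps the trailing body spline worm-shaped
    at low speeds; the measured angular-speed feature at low speed is instead
    dominated by head-swing jitter and reversal bursts, as in real dwelling.
    """
    rate = cfg.roam_turn_rate if state == STATE_ROAM else cfg.dwell_turn_rate
    ds = (cfg.roam_speed_mean if state == STATE_ROAM else cfg.dwell_speed_mean) / cfg.fps
    cap_deg = 380.0 * ds
    return math.radians(min(rate / cfg.fps, cap_deg))


class _Sim:
    def __init__(self, cfg: SimulationConfig):
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.fps = cfg.fps
        self.n = cfg.n_frames
        self.bin_frames = cfg.bin_frames
        self.n_bins = cfg.n_bins
        self.L = cfg.worm_length
        self.delta = self.L / (N_SPLINE - 1)
        self.head_off = 3.5 * self.delta     # head tip -> head-centroid arc offset
        self.cx, self.cy = cfg.lawn_center
        self.R = cfg.lawn_radius
        self.accel_frames = int(round(cfg.accel_motif.duration_s * cfg.fps))

        self.speed = {
            STATE_ROAM: cfg.roam_speed_mean,
            STATE_DWELL: cfg.dwell_speed_mean,
        }
        self.turn_sd = {s: _effective_turn_sd(cfg, s) for s in (STATE_ROAM, STATE_DWELL)}
        self.speed_scale = {
            s: _speed_scale(self.speed[s], self.turn_sd[s], cfg.speed_cv,
                            cfg.fps, cfg.worm_length)
            for s in (STATE_ROAM, STATE_DWELL)
        }

    # -- schedules ---------------------------------------------------------

    def _schedule(self) -> None:
        cfg, rng = self.cfg, self.rng
        self.states = _markov_states(cfg.p_stay_roam, cfg.p_stay_dwell,
                                     self.n_bins, rng, start=None)
        hazard = np.where(self.states == STATE_ROAM,
                          cfg.leave_hazard_roam, cfg.leave_hazard_dwell)
        if cfg.light_bins is not None:
            lit = np.zeros(self.n_bins, dtype=bool)
            idx = np.asarray(cfg.light_bins, dtype=int)
            lit[idx[idx < self.n_bins]] = True
            hazard = np.where(lit, np.minimum(hazard * cfg.light_leave_multiplier, 1.0),
                              hazard)
        draw = rng.random(self.n_bins)
        leave_bins = np.flatnonzero(draw < hazard)
        # roam run-in: an animal that leaves travels to the boundary at roam
        # speed through the acceleration motif, so the bins it spans (and the
        # leaving bin itself) are roam bins
        run_in = int(math.ceil(self.accel_frames / self.bin_frames))
        for b in leave_bins:
            self.states[max(0, int(b) - run_in): int(b) + 1] = STATE_ROAM
        self.leave_frames = [int(b) * self.bin_frames + self.bin_frames // 2
                             for b in leave_bins]

        n_pokes = rng.poisson(cfg.headpoke_rate * cfg.duration_s / 60.0)
        times = np.sort(rng.integers(0, self.n, size=n_pokes))
        types = rng.choice(
            [EVENT_HEAD_POKE_FORWARD, EVENT_HEAD_POKE_PAUSE, EVENT_HEAD_POKE_REVERSAL],
            size=n_pokes, p=np.asarray(cfg.poke_type_probs, dtype=float)
            / sum(cfg.poke_type_probs))
        self.pokes = list(zip(times.tolist(), types.tolist()))

        mean_rev_rate = 0.5 * (cfg.reversal_rate_roam_per_min
                               + cfg.reversal_rate_dwell_per_min)
        n_rev = rng.poisson(mean_rev_rate * cfg.duration_s / 60.0)
        self.rev_times = np.sort(rng.integers(0, self.n, size=n_rev)).tolist()
        # thinning: acceptance probability per state applied at trigger time
        self.rev_accept = {
            STATE_ROAM: cfg.reversal_rate_roam_per_min / max(mean_rev_rate, 1e-12),
            STATE_DWELL: cfg.reversal_rate_dwell_per_min / max(mean_rev_rate, 1e-12),
        }

        self.turn_z = rng.standard_normal(self.n)
        self.speed_ln = rng.lognormal(-cfg.speed_cv ** 2 / 2, cfg.speed_cv, self.n)

    # -- main loop ---------------------------------------------------------

    def run(self) -> tuple[Trajectory, LawnGeometry, GroundTruth]:
        cfg, rng = self.cfg, self.rng
        self._schedule()

        # burn-in: gently curled path ending at the start position
        n_burn = int(math.ceil((2 * self.L + 0.3) / self.delta))
        curv = math.radians(200.0) * self.delta        # 200 deg/mm spiral
        h0 = rng.uniform(0, 2 * math.pi)
        heads = h0 + curv * np.arange(n_burn)
        bx = np.concatenate([[0.0], np.cumsum(np.cos(heads) * self.delta)])
        by = np.concatenate([[0.0], np.cumsum(np.sin(heads) * self.delta)])
        r0 = 0.5 * self.R * math.sqrt(rng.random())
        a0 = rng.uniform(0, 2 * math.pi)
        start = np.array([self.cx + r0 * math.cos(a0), self.cy + r0 * math.sin(a0)])
        bx += start[0] - bx[-1]
        by += start[1] - by[-1]
        path = _Path(bx[0], by[0], float(heads[0]))
        for i in range(1, len(bx)):
            seg = math.hypot(bx[i] - bx[i - 1], by[i] - by[i - 1])
            path.px.append(float(bx[i]))
            path.py.append(float(by[i]))
            path.ps.append(path.ps[-1] + seg)
        path.heading = float(heads[-1])
        self.path = path
        self.s = path.end_s
        self.min_s = self.L + 0.05

        n = self.n
        self.S = np.empty((n, N_SPLINE, 2))
        self.frame_s = np.empty(n)
        self._flushed = 0
        v_cmd = np.empty(n)

        mode = "base"
        ctx: dict = {}
        poke_i = rev_i = leave_i = 0
        motifs: list[dict] = []
        poke_speed = max(cfg.roam_speed_mean, 2 * cfg.dwell_speed_mean)
        dash_frames = max(2, int(math.ceil(
            (0.25 + self.head_off + 0.05)
            / (cfg.roam_speed_mean * cfg.accel_motif.multiplier / cfg.fps))))

        for t in range(n):
            b = min(t // self.bin_frames, self.n_bins - 1)
            st = self.states[b]
            tip = path.pos_at(self.s) if self.s < path.end_s else (path.px[-1], path.py[-1])
            rho = math.hypot(tip[0] - self.cx, tip[1] - self.cy)
            d_in = self.R - rho                     # + inside the lawn
            to_center = math.atan2(self.cy - tip[1], self.cx - tip[0])
            outward = to_center + math.pi

            if mode == "base":
                if leave_i < len(self.leave_frames) and \
                        t >= self.leave_frames[leave_i] - self.accel_frames:
                    f_star = self.leave_frames[leave_i]
                    leave_i += 1
                    if d_in > 0.05 and t < f_star:
                        mode = "accel"
                        ctx = {"f_star": f_star, "t0": t,
                               "hand": 1.0 if rng.random() < 0.5 else -1.0,
                               "crossed_s": None}
                elif poke_i < len(self.pokes) and t >= self.pokes[poke_i][0]:
                    _, ptype = self.pokes[poke_i]
                    poke_i += 1
                    if 0.05 < d_in < 1.0:
                        mode = "poke_dash"
                        ctx = {"ptype": ptype, "t0": t}
                elif rev_i < len(self.rev_times) and t >= self.rev_times[rev_i]:
                    rev_i += 1
                    if d_in > 0.12 and rng.random() < min(self.rev_accept[st], 1.0):
                        k = 1 + rng.geometric(
                            1.0 / max(cfg.reversal_mean_s * cfg.fps, 1.0))
                        mode = "rev"
                        ctx = {"left": int(k)}

            if mode == "base":
                v = self.speed[st] * self.speed_ln[t] * self.speed_scale[st]
                dth = self.turn_sd[st] * self.turn_z[t]
                if d_in < 0.12:       # steer back toward the lawn interior
                    dth = max(-0.8, min(0.8, _ang_diff(to_center, path.heading)))
                path.extend(v / self.fps, dth)
                self.s = path.end_s

            elif mode == "accel":
                el = t - ctx["t0"]
                mult = 1.0 + (cfg.accel_motif.multiplier - 1.0) * min(
                    el / max(self.accel_frames, 1), 1.0)
                v = self.speed[st] * mult * self.speed_ln[t] * self.speed_scale[st]
                if t < ctx["f_star"] - dash_frames:
                    # hold a band ~0.25 mm inside the boundary, moving tangentially
                    ux, uy = ((tip[0] - self.cx) / max(rho, 1e-9),
                              (tip[1] - self.cy) / max(rho, 1e-9))
                    tx, ty = -uy * ctx["hand"], ux * ctx["hand"]
                    g = 3.0 * (d_in - 0.25)
                    th_des = math.atan2(ty + g * uy, tx + g * ux)
                    dth = max(-0.7, min(0.7, _ang_diff(th_des, path.heading)))
                    dth += 0.2 * self.turn_sd[STATE_ROAM] * self.turn_z[t]
                else:
                    v = cfg.roam_speed_mean * cfg.accel_motif.multiplier
                    dth = max(-1.0, min(1.0, _ang_diff(outward, path.heading)))
                    if d_in < 0 and ctx["crossed_s"] is None:
                        ctx["crossed_s"] = self.s
                path.extend(v / self.fps, dth)
                self.s = path.end_s
                if ctx["crossed_s"] is not None and \
                        self.s - ctx["crossed_s"] > self.L + 0.08:
                    motifs.append({"kind": EVENT_LEAVING, "t0": ctx["t0"], "t1": t})
                    mode = "offlawn"
                    ctx = {"left": int(rng.exponential(cfg.off_lawn_dwell_s) * cfg.fps)
                           + 1}
                elif el > self.accel_frames + 300:   # safety: could not exit
                    mode = "base"

            elif mode == "offlawn":
                v = cfg.roam_speed_mean * self.speed_ln[t]
                dth = self.turn_sd[STATE_ROAM] * self.turn_z[t]
                if d_in > -0.10:      # keep clear of the lawn until due back
                    dth = max(-0.8, min(0.8, _ang_diff(outward, path.heading)))
                elif d_in < -0.70:    # stay within the recorded arena
                    dth = max(-0.8, min(0.8, _ang_diff(to_center, path.heading)))
                path.extend(v / self.fps, dth)
                self.s = path.end_s
                ctx["left"] -= 1
                if ctx["left"] <= 0:
                    mode = "return"
                    ctx = {"crossed_s": None}

            elif mode == "return":
                v = cfg.roam_speed_mean * self.speed_ln[t]
                dth = max(-0.8, min(0.8, _ang_diff(to_center, path.heading)))
                path.extend(v / self.fps, dth)
                self.s = path.end_s
                if d_in > 0 and ctx["crossed_s"] is None:
                    ctx["crossed_s"] = self.s
                if ctx["crossed_s"] is not None and \
                        self.s - ctx["crossed_s"] > self.L + 0.05:
                    mode = "base"

            elif mode == "poke_dash":
                v = poke_speed
                dth = max(-1.2, min(1.2, _ang_diff(outward, path.heading)))
                path.extend(v / self.fps, dth)
                self.s = path.end_s
                depth_tip = -(self.R - math.hypot(path.px[-1] - self.cx,
                                                  path.py[-1] - self.cy))
                if depth_tip >= 0.12 + self.head_off:
                    ptype = ctx["ptype"]
                    if ptype == EVENT_HEAD_POKE_FORWARD:
                        mode = "poke_turn"
                        ctx["turn_left"] = 3
                        ctx["hand"] = 1.0 if rng.random() < 0.5 else -1.0
                    elif ptype == EVENT_HEAD_POKE_PAUSE:
                        # turn around first so the depth peak (the hairpin)
                        # precedes the pause; the pause then sits inside the
                        # post-peak recovery interval
                        mode = "poke_turn"
                        ctx["turn_left"] = 3
                        ctx["hand"] = 1.0 if rng.random() < 0.5 else -1.0
                    else:
                        mode = "poke_rev"
                elif t - ctx["t0"] > 120:
                    mode = "base"      # unreachable boundary; abandon
            elif mode == "poke_turn":
                v = poke_speed
                path.extend(v / self.fps, math.radians(60.0) * ctx["hand"])
                self.s = path.end_s
                ctx["turn_left"] -= 1
                if ctx["turn_left"] <= 0:
                    if ctx["ptype"] == EVENT_HEAD_POKE_PAUSE:
                        mode = "poke_clear"
                        ctx["left"] = 4
                    else:
                        mode = "poke_runin"
            elif mode == "poke_clear":
                # a few forward frames so the head segment clears the hairpin
                # (and its depth maximum) before the pause begins
                v = poke_speed
                dth = max(-0.8, min(0.8, _ang_diff(to_center, path.heading)))
                path.extend(v / self.fps, dth)
                self.s = path.end_s
                ctx["left"] -= 1
                if ctx["left"] <= 0:
                    mode = "poke_pause"
                    ctx["left"] = 24
            elif mode == "poke_pause":
                v = 0.004
                dth = max(-1.0, min(1.0, _ang_diff(to_center, path.heading)))
                path.extend(v / self.fps, dth)
                self.s = path.end_s
                ctx["left"] -= 1
                if ctx["left"] <= 0:
                    mode = "poke_runin"
            elif mode == "poke_rev":
                v = -0.7 * poke_speed
                new_s = max(self.s + v / self.fps, self.min_s)
                v = (new_s - self.s) * self.fps
                self.s = new_s
                tip2 = path.pos_at(self.s)
                d2 = self.R - math.hypot(tip2[0] - self.cx, tip2[1] - self.cy)
                if d2 > 0.10 + self.head_off or self.s <= self.min_s + 1e-9:
                    self.frame_s[t] = self.s
                    v_cmd[t] = v
                    self._finish_reversal(t, to_center, rng)
                    motifs.append({"kind": "head_poke",
                                   "subtype": EVENT_HEAD_POKE_REVERSAL,
                                   "t0": ctx["t0"], "t1": t})
                    mode = "base"
                    ctx = {}
                    continue
            elif mode == "poke_runin":
                v = poke_speed
                dth = max(-0.8, min(0.8, _ang_diff(to_center, path.heading)))
                path.extend(v / self.fps, dth)
                self.s = path.end_s
                if self.R - math.hypot(path.px[-1] - self.cx,
                                       path.py[-1] - self.cy) > 0.15:
                    motifs.append({"kind": "head_poke", "subtype": ctx["ptype"],
                                   "t0": ctx["t0"], "t1": t})
                    mode = "base"
                    ctx = {}
            elif mode == "rev":
                v = -self.speed[st] * self.speed_ln[t] * self.speed_scale[st]
                new_s = max(self.s + v / self.fps, self.min_s)
                v = (new_s - self.s) * self.fps
                self.s = new_s
                ctx["left"] -= 1
                if ctx["left"] <= 0 or self.s <= self.min_s + 1e-9:
                    self.frame_s[t] = self.s
                    v_cmd[t] = v
                    turn = rng.uniform(math.radians(60), math.radians(120))
                    turn *= 1.0 if rng.random() < 0.5 else -1.0
                    self._finish_reversal(t, path.heading + turn, rng, absolute=True)
                    mode = "base"
                    ctx = {}
                    continue

            self.frame_s[t] = self.s
            v_cmd[t] = v

        self._flush(n)
        return self._assemble(v_cmd, motifs)

    def _finish_reversal(self, t: int, new_heading: float,
                         rng: np.random.Generator, absolute: bool = True) -> None:
        """Flush sampled frames, drop the stale path ahead, set a new heading."""
        self._flush(t + 1)
        self.path.truncate(self.s)
        self.path.heading = new_heading

    def _flush(self, t_end: int) -> None:
        if t_end <= self._flushed:
            return
        xs, ys, ss = self.path.arrays()
        fr = np.arange(self._flushed, t_end)
        arcs = (self.frame_s[fr][:, None]
                - np.arange(N_SPLINE)[None, :] * self.delta).ravel()
        self.S[fr, :, 0] = np.interp(arcs, ss, xs).reshape(len(fr), N_SPLINE)
        self.S[fr, :, 1] = np.interp(arcs, ss, ys).reshape(len(fr), N_SPLINE)
        self._flushed = t_end

    # -- post-processing ---------------------------------------------------

    def _assemble(self, v_cmd: np.ndarray,
                  motifs: list[dict]) -> tuple[Trajectory, LawnGeometry, GroundTruth]:
        cfg, rng, n = self.cfg, self.rng, self.n
        S = self.S

        # lateral head swing on the first ~12 spline points
        phase0 = rng.uniform(0, 2 * math.pi)
        tgrid = np.arange(n) / cfg.fps
        osc = cfg.head_swing_amp * np.sin(
            2 * math.pi * tgrid / cfg.head_swing_period_s + phase0)
        w = np.zeros(N_SPLINE)
        w[:12] = ((12 - np.arange(12)) / 12.0) ** 2
        tang = np.empty_like(S)
        tang[:, 1:-1] = S[:, 2:] - S[:, :-2]
        tang[:, 0] = S[:, 1] - S[:, 0]
        tang[:, -1] = S[:, -1] - S[:, -2]
        norm = np.linalg.norm(tang, axis=2, keepdims=True)
        norm[norm < 1e-9] = 1.0
        normal = np.stack([-tang[..., 1], tang[..., 0]], axis=-1) / norm
        S = S + osc[:, None, None] * w[None, :, None] * normal

        centroid = S.mean(axis=1)
        visible = rng.random(n) >= cfg.missing_frac

        lawn = LawnGeometry.disk(cfg.lawn_center, cfg.lawn_radius,
                                 provenance="provided")
        gt = self._ground_truth(S, v_cmd, motifs, lawn)

        spline = S.copy()
        spline[~visible] = np.nan
        cen = centroid.copy()
        cen[~visible] = np.nan
        traj = Trajectory(
            fps=cfg.fps,
            time_s=tgrid,
            visible=visible,
            spline=spline,
            centroid=cen,
            pixel_scale=cfg.pixel_scale,
            animal_id=f"sim-{cfg.seed}",
            oriented=True,
        )
        return traj, lawn, gt

    def _ground_truth(self, S: np.ndarray, v_cmd: np.ndarray, motifs: list[dict],
                      lawn: LawnGeometry) -> GroundTruth:
        head = S[:, HEAD_SLICE].mean(axis=1)
        poly = lawn.polygon
        boundary = poly.exterior
        pts = shapely.points(head[:, 0], head[:, 1])
        dist = shapely.distance(pts, boundary)
        inside = shapely.contains_xy(poly, head[:, 0], head[:, 1])
        d = np.where(inside, dist, -dist)
        n = len(d)

        def body_all_outside(f: int) -> bool:
            return not shapely.contains_xy(poly, S[f, :, 0], S[f, :, 1]).any()

        def body_all_inside(f: int) -> bool:
            return shapely.contains_xy(poly, S[f, :, 0], S[f, :, 1]).all()

        events: list[BoundaryEvent] = []
        accel_onsets: list[int] = []
        for m in motifs:
            if m["kind"] == "head_poke":
                lo = max(m["t0"] - 2, 0)
                hi = min(m["t1"] + 3, n)
                neg = np.flatnonzero(d[lo:hi] < 0) + lo
                if len(neg) == 0:
                    continue
                start = int(neg[0])
                while start > 0 and d[start - 1] < 0:
                    start -= 1
                end = int(neg[-1]) + 1
                while end < n and d[end] < 0:
                    end += 1
                if end >= n:
                    continue
                run = slice(start, end)
                peak = start + int(np.argmin(d[run]))
                events.append(BoundaryEvent(m["subtype"], start, peak, end,
                                            float(d[peak])))
            elif m["kind"] == EVENT_LEAVING:
                seg = np.flatnonzero(d[m["t0"]:min(m["t1"] + 5, n)] < 0)
                if len(seg) == 0:
                    continue
                start = int(seg[0]) + m["t0"]
                f = start
                while f < n and not body_all_outside(f):
                    f += 1
                if f >= n:
                    continue
                end = f
                peak = start + int(np.argmin(d[start:end + 1]))
                events.append(BoundaryEvent(EVENT_LEAVING, start, peak, end,
                                            float(d[peak])))
                accel_onsets.append(max(start - self.accel_frames, 0))
                f2 = end + 1
                while f2 < n and not body_all_inside(f2):
                    f2 += 1
                if f2 < n:
                    events.append(BoundaryEvent(EVENT_REENTRY, f2, f2, f2,
                                                float(d[f2])))
        events.sort(key=lambda e: (e.start_frame, e.end_frame))

        state_per_frame = np.repeat(self.states, self.bin_frames)
        if len(state_per_frame) < n:
            state_per_frame = np.concatenate(
                [state_per_frame,
                 np.repeat(self.states[-1:], n - len(state_per_frame))])
        return GroundTruth(
            state_per_bin=self.states.copy(),
            events=events,
            accel_onsets=np.asarray(accel_onsets, dtype=int),
            commanded_speed=v_cmd,
            state_per_frame=state_per_frame[:n],
        )


def simulate_trajectory(config: SimulationConfig) -> tuple[Trajectory, LawnGeometry, GroundTruth]:
    """Simulate one animal; returns the trajectory, lawn polygon and ground truth."""
    return _Sim(config).run()


# ---------------------------------------------------------------------------
# deterministic fixture builder


def rigid_worm_trajectory(head_tip: np.ndarray, axis: np.ndarray, fps: float,
                          worm_length: float = 1.0,
                          pixel_scale: float | None = 0.01) -> Trajectory:
    """Deterministic straight-bodied worm, for hand-traceable fixtures.

    ``head_tip`` is the (T, 2) position of spline point 1 and ``axis`` the
    (T, 2) tail-to-head body direction per frame; the body extends
    ``worm_length`` behind the tip along ``-axis``.
    """
    head_tip = np.asarray(head_tip, dtype=float)
    axis = np.asarray(axis, dtype=float)
    u = axis / np.linalg.norm(axis, axis=1, keepdims=True)
    k = np.arange(N_SPLINE) * worm_length / (N_SPLINE - 1)
    spline = head_tip[:, None, :] - k[None, :, None] * u[:, None, :]
    T = len(head_tip)
    return Trajectory(
        fps=fps,
        time_s=np.arange(T) / fps,
        visible=np.ones(T, dtype=bool),
        spline=spline,
        centroid=spline.mean(axis=1),
        pixel_scale=pixel_scale,
        animal_id="scripted",
    )


# ---------------------------------------------------------------------------
# rendering


@dataclass
class RenderedMovie:
    """8-bit grayscale stack plus the mm coordinates of pixel (0, 0)."""

    stack: np.ndarray           # (T, H, W) uint8
    origin_mm: tuple[float, float]
    pixel_scale: float

    def to_pixels(self, xy_mm: np.ndarray) -> np.ndarray:
        """Map mm coordinates to (col, row) pixel coordinates."""
        return (np.asarray(xy_mm) - np.asarray(self.origin_mm)) / self.pixel_scale


AGAR_INTENSITY = 200
LAWN_INTENSITY = 180
WORM_INTENSITY = 60


def render_movie(trajectory: Trajectory, geometry: LawnGeometry, pixel_scale: float,
                 image_size: tuple[int, int] | None = None,
                 worm_width: float = 0.08) -> RenderedMovie:
    """Render a worm movie: dark worm tube, faint lawn disk, flat agar.

    Invisible frames are rendered without the worm. Raises if any visible
    spline point falls outside the image, naming the frame.
    """
    from skimage.draw import disk as draw_disk
    from skimage.draw import polygon as draw_polygon

    verts = geometry.vertices
    pts = trajectory.spline[trajectory.visible].reshape(-1, 2)
    pts = pts[np.isfinite(pts).all(axis=1)]
    all_xy = np.vstack([verts, pts]) if len(pts) else verts
    margin = 4 * worm_width
    if image_size is None:
        lo = all_xy.min(axis=0) - margin
        hi = all_xy.max(axis=0) + margin
        w = int(math.ceil((hi[0] - lo[0]) / pixel_scale))
        h = int(math.ceil((hi[1] - lo[1]) / pixel_scale))
        image_size = (h, w)
        origin = (float(lo[0]), float(lo[1]))
    else:
        h, w = image_size
        center = 0.5 * (all_xy.min(axis=0) + all_xy.max(axis=0))
        origin = (float(center[0] - w * pixel_scale / 2),
                  float(center[1] - h * pixel_scale / 2))

    background = np.full(image_size, AGAR_INTENSITY, dtype=np.uint8)
    vc = (verts[:, 0] - origin[0]) / pixel_scale
    vr = (verts[:, 1] - origin[1]) / pixel_scale
    rr, cc = draw_polygon(vr, vc, shape=image_size)
    background[rr, cc] = LAWN_INTENSITY

    radius = max(worm_width / 2 / pixel_scale, 1.0)
    stack = np.empty((trajectory.n_frames, *image_size), dtype=np.uint8)
    for f in range(trajectory.n_frames):
        frame = background.copy()
        if trajectory.visible[f]:
            sp = trajectory.spline[f]
            col = (sp[:, 0] - origin[0]) / pixel_scale
            row = (sp[:, 1] - origin[1]) / pixel_scale
            if (col.min() < radius or row.min() < radius
                    or col.max() >= image_size[1] - radius
                    or row.max() >= image_size[0] - radius):
                raise ValueError(f"worm out of frame at frame {f}")
            # densify so adjacent disks overlap into a solid tube
            fine = np.linspace(0, N_SPLINE - 1, 3 * N_SPLINE)
            fc = np.interp(fine, np.arange(N_SPLINE), col)
            fr_ = np.interp(fine, np.arange(N_SPLINE), row)
            for r_, c_ in zip(fr_, fc):
                rr, cc = draw_disk((r_, c_), radius, shape=image_size)
                frame[rr, cc] = WORM_INTENSITY
        stack[f] = frame
    return RenderedMovie(stack=stack, origin_mm=origin, pixel_scale=pixel_scale)
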