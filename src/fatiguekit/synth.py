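"""Seeded generators for every input the analysis pipeline consumes.

Three families:

* cued handgrip **force sessions** — trapezoidal contraction pulses toward a
  target force (a percentage of baseline MVC), with the per-contraction AUC
  drifting linearly at a configurable rate (the injected "fatigue"), plus
  additive Gaussian sample noise;
* **surface-EMG sessions** — band-limited (20-450 Hz) Gaussian carrier
  amplitude-modulated by the contraction gate, with a linear per-contraction
  amplitude drift;
* the **object-hit simulator** — balls released from 16 bins under a
  quota-constrained pseudorandom schedule fall toward two paddles driven by a
  bounded-speed pursuit policy with a reaction delay; collisions are detected
  by rectangle-circle overlap and deflected balls leave the workspace.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io import CueSchedule, Hit, Release, TaskLog, TimeSeries, build_cue_schedule

__all__ = [
    "ForceGenConfig",
    "EmgGenConfig",
    "PaddlePolicy",
    "ObjectHitConfig",
    "MapGenConfig",
    "gen_force_session",
    "gen_mvc_profile",
    "gen_emg_session",
    "simulate_object_hit",
    "gen_spatial_maps",
]

FORCE_RATE_HZ = 47.75
EMG_RATE_HZ = 2048.0


# ---------------------------------------------------------------------------
# force sessions


@dataclass(frozen=True)
class ForceGenConfig:
    """Cued handgrip session parameters.

    ``drift_beta`` is the injected linear drift of per-contraction AUC
    (force-au x s per contraction); the generator calibrates each pulse's
    amplitude against the same trapezoidal quadrature used by the analysis,
    so on noiseless output the fitted fatigue slope recovers ``drift_beta``
    to numerical precision.
    """

    mvc: float = 57.0
    target_pct: int = 75
    n_cycles: int = 270
    on_s: float = 1.0
    off_s: float = 1.0
    rise_s: float = 0.15
    fall_s: float = 0.15
    drift_beta: float = 0.0
    noise_sd: float = 0.0
    rate: float = FORCE_RATE_HZ

    def __post_init__(self) -> None:
        if self.target_pct not in (5, 50, 75):
            raise ValueError("target_pct must be one of 5, 50, 75")
        if self.rise_s + self.fall_s > self.on_s:
            raise ValueError("rise_s + fall_s must not exceed the contraction duration")
        if self.mvc <= 0 or self.n_cycles < 0 or self.rate <= 0 or self.noise_sd < 0:
            raise ValueError("invalid force generator configuration")

    @property
    def target_force(self) -> float:
        return self.target_pct / 100.0 * self.mvc

    @property
    def pulse_area_per_unit(self) -> float:
        """Analytic area of a unit-amplitude trapezoid pulse, in seconds."""
        return self.on_s - (self.rise_s + self.fall_s) / 2.0


def _unit_pulse(t: np.ndarray, start: float, cfg: ForceGenConfig) -> np.ndarray:
    """Unit-amplitude trapezoid over [start, start + on_s] evaluated at ``t``."""
    xp = [
        start,
        start + cfg.rise_s,
        start + cfg.on_s - cfg.fall_s,
        start + cfg.on_s,
    ]
    fp = [0.0, 1.0, 1.0, 0.0]
    out = np.interp(t, xp, fp)
    out[(t < start) | (t > start + cfg.on_s)] = 0.0
    return out


def gen_force_session(
    cfg: ForceGenConfig, seed: int | np.random.Generator | None = None
) -> tuple[TimeSeries, CueSchedule]:
    """Generate a cued force trace and its schedule.

    Contraction ``k`` targets a per-contraction AUC of
    ``A0 + drift_beta * k`` where ``A0`` is the AUC of a pulse whose plateau
    sits at the target force.  Amplitudes are clipped at zero if the drift
    would drive them negative.  Gaussian noise of SD ``noise_sd`` (force-au)
    is added to every sample.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    schedule = build_cue_schedule(cfg.n_cycles, cfg.on_s, cfg.off_s) if cfg.n_cycles else CueSchedule((), 0.0)
    duration = max(cfg.n_cycles * (cfg.on_s + cfg.off_s), cfg.on_s + cfg.off_s)
    n = int(round(duration * cfg.rate))
    t = np.arange(n) / cfg.rate
    values = np.zeros(n)

    a0 = cfg.target_force * cfg.pulse_area_per_unit
    n_seg = round(cfg.rate * cfg.on_s)
    dx = 1.0 / cfg.rate
    for k, (start, _end) in enumerate(schedule.cycles):
        i0 = round(start * cfg.rate)
        # pulse support may spill one sample past the analysis segment
        i1 = min(n, i0 + n_seg + 2)
        u = _unit_pulse(t[i0:i1], start, cfg)
        # calibrate against the trapezoid quadrature of the analysis segment
        a_unit = np.trapezoid(u[:n_seg], dx=dx)
        target_auc = max(0.0, a0 + cfg.drift_beta * k)
        amp = target_auc / a_unit if a_unit > 0 else 0.0
        values[i0:i1] += amp * u
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=n)
    trace = TimeSeries(t0=0.0, rate=cfg.rate, values=values, units="force-au", channel="grip-force")
    return trace, schedule


def gen_mvc_profile(
    amplitude: float,
    duration_s: float = 3.0,
    rate: float = FORCE_RATE_HZ,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> TimeSeries:
    """One maximal-contraction force profile: a smooth bell reaching ``amplitude``.

    The plateau region (half-power width) sits near ``amplitude``, so the
    FWHM-median summary of the profile is close to (and bounded by) it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    # raised-cosine bell with a flat centre
    v = amplitude * np.clip(1.5 * np.sin(np.pi * t / duration_s) ** 2, 0.0, 1.0)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)
    return TimeSeries(t0=0.0, rate=rate, values=v, units="force-au", channel="mvc")


# ---------------------------------------------------------------------------
# EMG sessions


@dataclass(frozen=True)
class EmgGenConfig:
    """Amplitude-modulated band-limited EMG surrogate.

    The carrier is Gaussian noise bandpassed to ``band`` and normalised to
    unit RMS; during contraction ``k`` it is scaled by
    ``amplitude * max(0, 1 + drift_per_contraction * k)`` through a smooth
    gate with ``gate_edge_s`` rise/fall ramps.
    """

    n_cycles: int = 270
    on_s: float = 1.0
    off_s: float = 1.0
    amplitude: float = 1.0
    drift_per_contraction: float = 0.0
    band: tuple[float, float] = (20.0, 450.0)
    gate_edge_s: float = 0.05
    rate: float = EMG_RATE_HZ

    def __post_init__(self) -> None:
        if self.rate <= 2 * self.band[1]:
            raise ValueError("rate must exceed twice the upper band edge")
        if 2 * self.gate_edge_s > self.on_s:
            raise ValueError("gate edges must fit inside the contraction window")


def gen_emg_session(
    cfg: EmgGenConfig, seed: int | np.random.Generator | None = None, gate_on: bool = True
) -> tuple[TimeSeries, CueSchedule]:
    """Generate a synthetic EMG trace and the matching cue schedule."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    schedule = build_cue_schedule(cfg.n_cycles, cfg.on_s, cfg.off_s)
    duration = cfg.n_cycles * (cfg.on_s + cfg.off_s)
    n = int(round(duration * cfg.rate))
    t = np.arange(n) / cfg.rate

    carrier = rng.standard_normal(n)
    sos = signal.butter(4, list(cfg.band), btype="bandpass", fs=cfg.rate, output="sos")
    carrier = signal.sosfiltfilt(sos, carrier)
    carrier /= np.sqrt(np.mean(carrier**2))

    gate = np.zeros(n)
    if gate_on:
        e = cfg.gate_edge_s
        for k, (start, end) in enumerate(schedule.cycles):
            g_k = max(0.0, 1.0 + cfg.drift_per_contraction * k)
            xp = [start, start + e, end - e, end]
            fp = [0.0, g_k, g_k, 0.0]
            i0 = int(math.floor(start * cfg.rate))
            i1 = min(n, int(math.ceil(end * cfg.rate)) + 1)
            seg = np.interp(t[i0:i1], xp, fp)
            seg[(t[i0:i1] < start) | (t[i0:i1] > end)] = 0.0
            gate[i0:i1] = np.maximum(gate[i0:i1], seg)

    values = cfg.amplitude * gate * carrier
    trace = TimeSeries(t0=0.0, rate=cfg.rate, values=values, units="au", channel="emg")
    return trace, schedule


# ---------------------------------------------------------------------------
# object-hit simulator


@dataclass(frozen=True)
class PaddlePolicy:
    """Bounded-speed pursuit controller for one paddle.

    The paddle commits to the most imminent target (lowest descending unhit
    ball in its half of the workspace) no sooner than ``reaction_delay`` after
    first selecting it, then moves toward the interception point with a
    proportional controller capped at ``max_speed``.
    """

    reaction_delay: float = 0.15
    max_speed: float = 60.0
    gain: float = 8.0
    park: tuple[float, float] | None = None  # fixed position; overrides pursuit


@dataclass(frozen=True)
class ObjectHitConfig:
    """Geometry and schedule of the bimanual object-hit task.

    Defaults mirror the assessment protocol: 480 balls (16 bins x 30) at two
    per second over 4 min, falling at 15-30 cm/s through a 76 x 44 cm
    workspace toward 1.5 x 0.5 cm paddles; balls are 0.75 cm across.
    """

    n_bins: int = 16
    objects_per_bin: int = 30
    speed_min: float = 15.0
    speed_max: float = 30.0
    release_rate: float = 2.0
    duration: float = 240.0
    workspace: tuple[float, float] = (76.0, 44.0)
    paddle_w: float = 1.5
    paddle_h: float = 0.5
    ball_diameter: float = 0.75
    rate: float = 200.0
    paddle_y_home: float = 6.0
    left: PaddlePolicy = field(default_factory=PaddlePolicy)
    right: PaddlePolicy = field(default_factory=PaddlePolicy)

    def __post_init__(self) -> None:
        if self.n_bins * self.objects_per_bin != round(self.release_rate * self.duration):
            raise ValueError(
                "infeasible schedule: n_bins * objects_per_bin must equal "
                "release_rate * duration"
            )
        if self.speed_min <= 0 or self.speed_max < self.speed_min:
            raise ValueError("invalid speed range")


class _Ball:
    __slots__ = ("x", "y", "vx", "vy", "bin", "hit", "active")

    def __init__(self, x: float, y: float, vy: float, bin_: int):
        self.x, self.y = x, y
        self.vx, self.vy = 0.0, vy
        self.bin = bin_
        self.hit = False
        self.active = True


def _rect_circle_hit(px: float, py: float, hw: float, hh: float, bx: float, by: float, r: float) -> bool:
    cx = min(max(bx, px - hw), px + hw)
    cy = min(max(by, py - hh), py + hh)
    return (bx - cx) ** 2 + (by - cy) ** 2 <= r * r


def simulate_object_hit(
    cfg: ObjectHitConfig, seed: int | np.random.Generator | None = None
) -> TaskLog:
    """Run one object-hit session and return its event log.

    Releases are quota-constrained (exactly ``objects_per_bin`` per bin) with
    pseudorandom bin order and uniform speeds; hits deflect the ball with a
    vertical velocity sign flip plus a horizontal component proportional to
    the contact offset.  Each ball can be hit at most once, and only while it
    is inside the workspace.  Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W, H = cfg.workspace
    n_rel = cfg.n_bins * cfg.objects_per_bin
    bins = rng.permutation(np.repeat(np.arange(cfg.n_bins), cfg.objects_per_bin))
    speeds = rng.uniform(cfg.speed_min, cfg.speed_max, size=n_rel)
    release_times = np.arange(n_rel) / cfg.release_rate
    bin_w = W / cfg.n_bins

    releases = [
        Release(time=float(release_times[k]), bin=int(bins[k]), speed=float(speeds[k]))
        for k in range(n_rel)
    ]
    hits: list[Hit] = []

    dt = 1.0 / cfg.rate
    n_steps = int(round(cfg.duration * cfg.rate))
    hw, hh = cfg.paddle_w / 2.0, cfg.paddle_h / 2.0
    r = cfg.ball_diameter / 2.0

    pos = {
        "left": np.array([W * 0.25, cfg.paddle_y_home]),
        "right": np.array([W * 0.75, cfg.paddle_y_home]),
    }
    policies = {"left": cfg.left, "right": cfg.right}
    committed: dict[str, _Ball | None] = {"left": None, "right": None}
    pending: dict[str, tuple[_Ball, float] | None] = {"left": None, "right": None}
    traj = {hand: np.empty((n_steps, 2)) for hand in pos}

    balls: list[_Ball] = []
    next_release = 0

    for step in range(n_steps):
        t = step * dt
        while next_release < n_rel and release_times[next_release] <= t:
            k = next_release
            balls.append(_Ball((bins[k] + 0.5) * bin_w, H, -speeds[k], int(bins[k])))
            next_release += 1

        for ball in balls:
            if ball.active:
                ball.x += ball.vx * dt
                ball.y += ball.vy * dt
                if ball.y < -1.0 or ball.y > H + 1.0 or ball.x < -1.0 or ball.x > W + 1.0:
                    ball.active = False
        balls = [b for b in balls if b.active]

        for hand in ("left", "right"):
            pol = policies[hand]
            if pol.park is not None:
                pos[hand][:] = pol.park
                traj[hand][step] = pos[hand]
                continue
            lo, hi = (0.0, W / 2.0) if hand == "left" else (W / 2.0, W)
            candidates = [
                b for b in balls if not b.hit and b.vy < 0 and lo <= b.x < hi
            ]
            want = min(candidates, key=lambda b: b.y, default=None)
            if want is not committed[hand]:
                if pending[hand] is None or pending[hand][0] is not want:
                    pending[hand] = (want, t + pol.reaction_delay) if want else None
                    if want is None:
                        committed[hand] = None
                elif t >= pending[hand][1]:
                    committed[hand] = pending[hand][0]
                    pending[hand] = None
            tgt_ball = committed[hand]
            if tgt_ball is not None and (tgt_ball.hit or not tgt_ball.active):
                committed[hand] = tgt_ball = None
            if tgt_ball is not None:
                target = np.array(
                    [tgt_ball.x, min(max(tgt_ball.y, 3.0), cfg.paddle_y_home + 6.0)]
                )
            else:
                target = np.array([(lo + hi) / 2.0, cfg.paddle_y_home])
            v = pol.gain * (target - pos[hand])
            speed = float(np.hypot(*v))
            if speed > pol.max_speed > 0:
                v *= pol.max_speed / speed
            elif pol.max_speed == 0:
                v[:] = 0.0
            pos[hand] += v * dt
            pos[hand][0] = min(max(pos[hand][0], 0.0), W)
            pos[hand][1] = min(max(pos[hand][1], 0.0), H)
            traj[hand][step] = pos[hand]

        for ball in balls:
            if ball.hit or not (0.0 <= ball.x <= W and 0.0 <= ball.y <= H):
                continue
            touching = [
                hand
                for hand in ("left", "right")
                if _rect_circle_hit(pos[hand][0], pos[hand][1], hw, hh, ball.x, ball.y, r)
            ]
            if not touching:
                continue
            hand = min(
                touching, key=lambda h: (pos[h][0] - ball.x) ** 2 + (pos[h][1] - ball.y) ** 2
            )
            ball.hit = True
            ball.vy = abs(ball.vy)
            ball.vx += (ball.x - pos[hand][0]) / hw * 10.0
            hits.append(Hit(time=t, hand=hand, bin=ball.bin))

    trajectories = {
        hand: (
            TimeSeries(t0=0.0, rate=cfg.rate, values=traj[hand][:, 0], units="cm", channel=f"{hand}-x"),
            TimeSeries(t0=0.0, rate=cfg.rate, values=traj[hand][:, 1], units="cm", channel=f"{hand}-y"),
        )
        for hand in traj
    }
    return TaskLog(releases=releases, hits=hits, trajectories=trajectories, duration=cfg.duration)


# ---------------------------------------------------------------------------
# spatial map sets


@dataclass(frozen=True)
class MapGenConfig:
    """Normal-noise spatial maps with an optional block effect in group 2."""

    height: int = 30
    width: int = 30
    n_per_group: int = 20
    effect_rows: tuple[int, int] = (0, 0)  # half-open row range of the effect block
    effect_cols: tuple[int, int] = (0, 0)
    effect_size: float = 0.0  # SD units added in group 2

    def __post_init__(self) -> None:
        if not (0 <= self.effect_rows[0] <= self.effect_rows[1] <= self.height):
            raise ValueError("effect_rows out of grid")
        if not (0 <= self.effect_cols[0] <= self.effect_cols[1] <= self.width):
            raise ValueError("effect_cols out of grid")


def gen_spatial_maps(cfg: MapGenConfig, seed: int | np.random.Generator | None = None):
    """i.i.d. standard-normal map set, two groups, seeded; effect added to group 2."""
    from .cluster import SpatialMapSet

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cfg.n_per_group
    maps = rng.standard_normal((2 * n, cfg.height, cfg.width))
    r0, r1 = cfg.effect_rows
    c0, c1 = cfg.effect_cols
    maps[n:, r0:r1, c0:c1] += cfg.effect_size
    labels = np.array(["A"] * n + ["B"] * n)
    return SpatialMapSet(maps=maps, labels=labels)
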