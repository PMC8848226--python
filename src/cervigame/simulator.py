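"""Synthetic users and synthetic IMU signals.

The simulator closes the loop around the rest of the package without
hardware: a parametric head-kinematics model pursues the scheduled
targets, and an inverse sensor model turns any angular trajectory into
the raw gyroscope/accelerometer/magnetometer stream a head-mounted IMU
would have produced.

The user model captures the behavioural ingredients that shape game
scores: a reaction delay after each target appears, a bounded angular
speed, motor noise (a per-target aiming error plus continuous tremor),
an engagement probability, and session-to-session learning modelled as
a multiplicative decay of the motor noise — emulating the progressive
rise of success percentages across training sessions.

Pursuit dynamics are first-order: the head approaches the aimed angles
exponentially with time constant ``tau_s``, with the angular rate capped
at ``max_angular_speed``.  Between goal switches this has a closed form
(a constant-rate phase while the demanded rate exceeds the cap, then an
exponential tail), which the simulator evaluates segment by segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as _sig
from scipy.spatial.transform import Rotation as _Rotation

from .engine import GameConfig, SessionLog, TargetSpec, generate_targets, run_session
from .fusion import GRAVITY_WORLD, MAG_WORLD, ImuStream
from .mapping import MappingConfig, angles_for_position
from .rotation import EulerYZX

__all__ = [
    "UserModel",
    "ImuNoise",
    "PursuitTrajectory",
    "simulate_pursuit",
    "synthesize_imu",
    "simulate_session",
    "simulate_protocol",
]


@dataclass(frozen=True)
class UserModel:
    """Behavioural parameters of a simulated player.

    reaction_delay:
        Seconds between a target appearing and the head starting to
        move toward it.
    max_angular_speed:
        Cap on the head angular rate per axis, deg/s (``math.inf``
        allowed).
    motor_noise_sd:
        Degrees.  Drawn once per target as an aiming error on each
        control axis; a quarter of it also drives a correlated tremor
        wander superimposed on the smooth pursuit.  The default is
        calibrated so a first-session player reaches about 69% of
        targets under the default protocol.
    hit_commitment:
        Probability that a given target is pursued at all.
    learning_rate:
        Multiplicative decay of ``motor_noise_sd`` per session
        (1 = no learning).
    tau_s:
        Time constant of the first-order pursuit, seconds.
    """

    reaction_delay: float = 0.4
    max_angular_speed: float = 60.0
    motor_noise_sd: float = 3.2
    hit_commitment: float = 1.0
    learning_rate: float = 0.9
    tau_s: float = 0.3

    def __post_init__(self) -> None:
        if self.reaction_delay < 0 or self.motor_noise_sd < 0:
            raise ValueError("delays and noise must be non-negative")
        if self.max_angular_speed < 0:
            raise ValueError("max_angular_speed must be non-negative")
        if not 0.0 <= self.hit_commitment <= 1.0:
            raise ValueError("hit_commitment must lie in [0, 1]")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")


@dataclass(frozen=True)
class ImuNoise:
    """Additive sensor noise: white noise per channel and a constant gyro bias."""

    gyro_sd: float = 0.2  # deg/s
    gyro_bias: float = 0.05  # deg/s, drawn once per stream per axis
    accel_sd: float = 0.01  # g
    mag_sd: float = 0.01  # normalized units

    def __post_init__(self) -> None:
        if min(self.gyro_sd, self.gyro_bias, self.accel_sd, self.mag_sd) < 0:
            raise ValueError("noise magnitudes must be non-negative")

    @classmethod
    def none(cls) -> "ImuNoise":
        return cls(0.0, 0.0, 0.0, 0.0)


class PursuitTrajectory:
    """Ground-truth head angles over a session, on a uniform time grid.

    ``alpha`` is flexion-extension; the horizontal-control angle lands
    on ``incl`` or ``rot`` according to the mapping's
    ``horizontal_source``, the third angle staying zero.  Iterating
    yields ``(t, EulerYZX)`` pairs.
    """

    def __init__(self, t: np.ndarray, alpha: np.ndarray, rot: np.ndarray,
                 incl: np.ndarray):
        self.t = t
        self.alpha = alpha
        self.rot = rot
        self.incl = incl

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self):
        for i in range(len(self.t)):
            yield float(self.t[i]), EulerYZX(
                float(self.alpha[i]), float(self.rot[i]), float(self.incl[i])
            )

    def cursor_samples(self, cfg: MappingConfig) -> np.ndarray:
        """Map the angles through the cursor law; returns (n, 3) of t, x, y."""
        beta = self.incl if cfg.horizontal_source == "inclination" else self.rot
        x = np.clip(cfg.r_h * beta / cfg.beta_t, -cfg.screen_w / 2, cfg.screen_w / 2)
        y = np.clip(-cfg.r_v * self.alpha / cfg.alpha_t, -cfg.screen_h / 2,
                    cfg.screen_h / 2)
        return np.column_stack([self.t, x, y])


def _pursuit_axis(
    t: np.ndarray,
    switch_times: np.ndarray,
    goals: np.ndarray,
    start: float,
    vmax: float,
    tau: float,
) -> np.ndarray:
    """Closed-form rate-limited first-order pursuit of a piecewise-constant goal."""
    out = np.empty_like(t)
    a0 = start
    bounds = np.concatenate([switch_times, [t[-1] + 1.0]])
    # samples before the first switch hold the start value
    out[t < bounds[0]] = a0
    for k in range(len(goals)):
        mask = (t >= bounds[k]) & (t < bounds[k + 1])
        seg_t = t[mask] - bounds[k]
        g = goals[k]
        delta = g - a0
        if vmax == 0.0:
            out[mask] = a0
            continue
        s = math.copysign(1.0, delta) if delta != 0 else 0.0
        amp = min(abs(delta), vmax * tau)
        t_lin = max(0.0, (abs(delta) - vmax * tau) / vmax) if math.isfinite(vmax) else 0.0
        out_seg = np.empty_like(seg_t)
        lin = (seg_t <= t_lin) if t_lin > 0.0 else np.zeros(len(seg_t), dtype=bool)
        if t_lin > 0.0:
            out_seg[lin] = a0 + s * vmax * seg_t[lin]
        out_seg[~lin] = g - s * amp * np.exp(-(seg_t[~lin] - t_lin) / tau)
        out[mask] = out_seg
        # state at the end of the segment seeds the next one
        seg_len = bounds[k + 1] - bounds[k]
        if seg_len <= t_lin:
            a0 = a0 + s * vmax * seg_len
        else:
            a0 = g - s * amp * math.exp(-(seg_len - t_lin) / tau)
    return out


#: correlation time of the tremor/wander process, seconds
TREMOR_TAU_S = 0.5


def _tremor(n: int, sd: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) angular wander, sd degrees, ~0.5 s correlation time.

    Physiological tremor and postural wander are low-frequency; white
    per-sample jitter would give a player hundreds of independent
    chances per target window and grossly inflate hit rates.
    """
    if sd <= 0:
        return np.zeros((n, 2))
    rho = math.exp(-dt / TREMOR_TAU_S)
    eps = rng.normal(0.0, sd, size=(n, 2))
    c = math.sqrt(1.0 - rho * rho)
    return _sig.lfilter([c], [1.0, -rho], eps, axis=0)


def simulate_pursuit(
    targets: Sequence[TargetSpec],
    user: UserModel,
    cfg: MappingConfig,
    rng: np.random.Generator,
    sample_rate: float = 50.0,
) -> PursuitTrajectory:
    """Simulate the head angles of a player pursuing the scheduled targets.

    The head starts at the neutral posture (all angles zero) and, after
    ``reaction_delay`` from each spawn, pursues the target's required
    angles perturbed by a per-target aiming error; per-sample tremor is
    superimposed on the smooth trajectory.  Uncommitted targets (with
    probability ``1 − hit_commitment``) are simply not pursued.
    """
    if not targets:
        raise ValueError("no targets to pursue")
    duration = max(tg.deadline_t for tg in targets)
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    switch = np.array([tg.spawn_t + user.reaction_delay for tg in targets])
    goal_a = np.empty(len(targets))
    goal_b = np.empty(len(targets))
    aim_err = rng.normal(0.0, user.motor_noise_sd, size=(len(targets), 2))
    committed = rng.random(len(targets)) < user.hit_commitment
    prev = (0.0, 0.0)
    for i, tg in enumerate(targets):
        if committed[i]:
            alpha, beta = angles_for_position(tg.position, cfg)
            goal = (alpha + aim_err[i, 0], beta + aim_err[i, 1])
        else:
            goal = prev  # stays wherever it was heading
        goal_a[i], goal_b[i] = goal
        prev = goal
    tremor = _tremor(n, user.motor_noise_sd / 4.0, 1.0 / sample_rate, rng)
    alpha = _pursuit_axis(t, switch, goal_a, 0.0, user.max_angular_speed, user.tau_s)
    beta = _pursuit_axis(t, switch, goal_b, 0.0, user.max_angular_speed, user.tau_s)
    alpha = alpha + tremor[:, 0]
    beta = beta + tremor[:, 1]
    zero = np.zeros(n)
    if cfg.horizontal_source == "inclination":
        return PursuitTrajectory(t, alpha, zero, beta)
    return PursuitTrajectory(t, alpha, beta, zero)


def synthesize_imu(
    trajectory: PursuitTrajectory,
    noise: ImuNoise | None = None,
    rng: np.random.Generator | None = None,
) -> ImuStream:
    """Generate the raw IMU stream a head-mounted sensor would record.

    The angular trajectory is composed into orientations; the gyroscope
    reports the head-frame finite-difference angular velocity plus bias
    and white noise, the accelerometer the gravity direction rotated
    into the head frame (specific force of a quasi-static motion, in g)
    and the magnetometer the rotated reference field.
    """
    if len(trajectory) < 2:
        raise ValueError("need at least 2 samples to synthesize an IMU stream")
    if noise is None:
        noise = ImuNoise.none()
    if rng is None:
        rng = np.random.default_rng(0)
    t = trajectory.t
    ang = np.column_stack([trajectory.alpha, trajectory.rot, trajectory.incl])
    rots = _Rotation.from_euler("YZX", ang, degrees=True)
    n = len(t)
    # body-frame angular velocity over [k, k+1]; the last sample repeats
    rel = rots[:-1].inv() * rots[1:]
    dt = np.diff(t)
    gyro = rel.as_rotvec(degrees=True) / dt[:, None]
    gyro = np.vstack([gyro, gyro[-1]])
    inv = rots.inv()
    accel = inv.apply(np.tile(GRAVITY_WORLD, (n, 1)))
    mag = inv.apply(np.tile(MAG_WORLD, (n, 1)))
    bias = rng.normal(0.0, noise.gyro_bias, size=3) if noise.gyro_bias > 0 else np.zeros(3)
    if noise.gyro_sd > 0:
        gyro = gyro + rng.normal(0.0, noise.gyro_sd, size=(n, 3))
    gyro = gyro + bias
    if noise.accel_sd > 0:
        accel = accel + rng.normal(0.0, noise.accel_sd, size=(n, 3))
    if noise.mag_sd > 0:
        mag = mag + rng.normal(0.0, noise.mag_sd, size=(n, 3))
    return ImuStream.from_arrays(t, gyro, accel, mag)


def simulate_session(
    user: UserModel,
    cfg: GameConfig,
    rng: np.random.Generator,
    sample_rate: float = 50.0,
) -> SessionLog:
    """One full session: target generation, pursuit, mapping, scoring."""
    targets = generate_targets(cfg, rng)
    traj = simulate_pursuit(targets, user, cfg.mapping, rng, sample_rate)
    cursor = traj.cursor_samples(cfg.mapping)
    return run_session(cfg, map(tuple, cursor), targets=targets)


def simulate_protocol(
    user: UserModel,
    cfg: GameConfig,
    n_sessions: int,
    rng: np.random.Generator,
    sample_rate: float = 50.0,
) -> list[float]:
    """Score series over a training protocol with session-to-session learning.

    The motor noise shrinks by ``learning_rate`` each session
    (``sd_k = motor_noise_sd · learning_rate^k``); everything else is
    held fixed.  The study protocol corresponds to ``n_sessions = 8``
    (twice a week for four weeks).
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    scores = []
    for k in range(n_sessions):
        u = replace(user, motor_noise_sd=user.motor_noise_sd * user.learning_rate ** k)
        log = simulate_session(u, cfg, rng, sample_rate)
        scores.append(log.score_percent)
    return scores
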