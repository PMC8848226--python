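"""Headless target-reaching game engine.

A session schedules a fixed number of targets at a fixed cadence
(the study protocol: 2 series of 21 targets, one every 5 s, 210 s in
total).  Target positions are drawn uniformly over the angular range of
motion box and shown one at a time; a target is *reached* when the
cursor enters its radius before the next target is due, otherwise it is
*missed*.  The engine records the airplane trajectory, the per-target
outcomes and the percentage score, mirroring what the original
application stores in its session database.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .mapping import CursorPosition, MappingConfig, angles_for_position

__all__ = [
    "GameConfig",
    "TargetSpec",
    "TargetOutcome",
    "SessionLog",
    "generate_targets",
    "run_session",
    "score_session",
    "series_scores",
    "trajectory_metrics",
]


@dataclass(frozen=True)
class GameConfig:
    """Session protocol settings.

    Defaults reproduce the pilot protocol: 21 targets per series, two
    series, a 5-second cadence (210 s per session) and an easy-level
    required range of motion of 25°, with lateral inclination as the
    horizontal control and axial rotation unworked.
    """

    targets_per_series: int = 21
    n_series: int = 2
    inter_target_s: float = 5.0
    target_radius: float = 40.0
    mapping: MappingConfig = field(default_factory=MappingConfig)
    required_rom: float = 25.0
    min_separation: float = 5.0
    seed: int = 0
    difficulty_label: str = "easy"

    def __post_init__(self) -> None:
        if self.targets_per_series < 1:
            raise ValueError("targets_per_series must be >= 1")
        if self.n_series < 1:
            raise ValueError("n_series must be >= 1")
        if self.inter_target_s <= 0:
            raise ValueError("inter_target_s must be positive")
        if self.target_radius <= 0:
            raise ValueError("target_radius must be positive")
        if self.required_rom <= 0:
            raise ValueError("required_rom must be positive")
        if self.required_rom > min(self.mapping.alpha_t * self.mapping.screen_h
                                   / (2 * self.mapping.r_v),
                                   self.mapping.beta_t * self.mapping.screen_w
                                   / (2 * self.mapping.r_h)):
            raise ValueError("required_rom places targets off screen")
        if self.min_separation < 0:
            raise ValueError("min_separation must be non-negative")

    @property
    def total_targets(self) -> int:
        return self.targets_per_series * self.n_series

    @property
    def session_duration_s(self) -> float:
        return self.total_targets * self.inter_target_s


@dataclass(frozen=True)
class TargetSpec:
    """One scheduled target: screen position and its time window."""

    index: int
    position: CursorPosition
    spawn_t: float
    deadline_t: float


@dataclass(frozen=True)
class TargetOutcome:
    index: int
    reached: bool
    time_to_hit: float | None  # seconds from spawn; None when missed


@dataclass
class SessionLog:
    """Everything a session stores: config snapshot, trajectory, outcomes, score."""

    config: GameConfig
    targets: list[TargetSpec]
    trajectory: list[tuple[float, float, float]]  # (t, x, y)
    outcomes: list[TargetOutcome]

    @property
    def n_reached(self) -> int:
        return sum(o.reached for o in self.outcomes)

    @property
    def n_missed(self) -> int:
        return sum(not o.reached for o in self.outcomes)

    @property
    def score_percent(self) -> float:
        return score_session(self)

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "targets": [asdict(t) for t in self.targets],
            "outcomes": [asdict(o) for o in self.outcomes],
            "n_reached": self.n_reached,
            "n_missed": self.n_missed,
            "score_percent": self.score_percent,
            "series_scores": series_scores(self),
        }
        return json.dumps(payload, indent=2)


def generate_targets(cfg: GameConfig, rng: np.random.Generator) -> list[TargetSpec]:
    """Draw the session's target sequence.

    Positions are uniform over the angular box ±``required_rom`` on both
    control axes (mapped to pixels through the session's mapping law),
    re-drawn until each target sits at least ``min_separation`` degrees
    from its predecessor.  Spawn times fall at multiples of the cadence;
    a fixed seed reproduces the sequence exactly.
    """
    specs: list[TargetSpec] = []
    prev_angles: tuple[float, float] | None = None
    rom = cfg.required_rom
    m = cfg.mapping
    for k in range(cfg.total_targets):
        for attempt in range(1000):
            alpha = float(rng.uniform(-rom, rom))
            beta = float(rng.uniform(-rom, rom))
            if m.mode == "1D-vertical":
                beta = 0.0
            elif m.mode == "1D-horizontal":
                alpha = 0.0
            if prev_angles is None or math.hypot(
                alpha - prev_angles[0], beta - prev_angles[1]
            ) >= cfg.min_separation:
                break
        else:
            raise RuntimeError(
                "could not place a target min_separation away from the previous "
                "one; required_rom is too small for min_separation"
            )
        x = m.r_h * beta / m.beta_t
        y = -m.r_v * alpha / m.alpha_t
        spawn = k * cfg.inter_target_s
        specs.append(
            TargetSpec(
                index=k,
                position=CursorPosition(x, y),
                spawn_t=spawn,
                deadline_t=spawn + cfg.inter_target_s,
            )
        )
        prev_angles = (alpha, beta)
    return specs


def run_session(
    cfg: GameConfig,
    cursor_source: Iterable[tuple[float, float, float]],
    targets: Sequence[TargetSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> SessionLog:
    """Play one session against a cursor stream.

    ``cursor_source`` yields ``(t, x, y)`` samples — from the mapping
    over a fused IMU stream, a replayed trajectory log, or the simulated
    user.  One target is active at a time; the first sample strictly
    inside its radius during ``[spawn_t, deadline_t)`` scores a hit.
    The stream must cover the whole session.
    """
    if targets is None:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        targets = generate_targets(cfg, rng)
    arr = np.asarray([(t, x, y) for t, x, y in cursor_source], dtype=float)
    if arr.ndim != 2 or (arr.size and arr.shape[1] != 3):
        raise ValueError("cursor_source must yield (t, x, y) samples")
    if arr.size and np.any(np.diff(arr[:, 0]) < 0):
        raise ValueError("cursor timestamps must be non-decreasing")
    trajectory: list[tuple[float, float, float]] = [tuple(row) for row in arr]
    hits: dict[int, float] = {}
    duration = cfg.session_duration_s
    ts = arr[:, 0] if arr.size else np.empty(0)
    for tg in targets:
        lo = np.searchsorted(ts, tg.spawn_t, side="left")
        hi = np.searchsorted(ts, tg.deadline_t, side="left")
        if lo == hi:
            continue
        d = np.hypot(
            arr[lo:hi, 1] - tg.position.x, arr[lo:hi, 2] - tg.position.y
        )
        inside = np.flatnonzero(d < cfg.target_radius)
        if inside.size:
            hits[tg.index] = float(ts[lo + inside[0]] - tg.spawn_t)
    # the stream must cover the session up to (at least) one sample period
    # short of the final deadline
    if len(trajectory) >= 2:
        slack = max(0.1, 2.0 * float(np.median(np.diff([p[0] for p in trajectory]))))
    else:
        slack = 0.1
    if not trajectory or trajectory[-1][0] < duration - slack:
        end = trajectory[-1][0] if trajectory else 0.0
        raise ValueError(
            f"cursor stream ends at {end:.2f} s but the session lasts "
            f"{duration:.2f} s"
        )
    outcomes = [
        TargetOutcome(index=tg.index, reached=tg.index in hits,
                      time_to_hit=hits.get(tg.index))
        for tg in targets
    ]
    return SessionLog(config=cfg, targets=list(targets), trajectory=trajectory,
                      outcomes=outcomes)


def score_session(log: SessionLog) -> float:
    """Session score: percentage of scheduled targets reached, all series pooled."""
    if not log.outcomes:
        raise ValueError("session log has no target outcomes")
    return 100.0 * log.n_reached / len(log.outcomes)


def series_scores(log: SessionLog) -> list[float]:
    """Per-series percentages (the day's score is their mean)."""
    n = log.config.targets_per_series
    out = []
    for s in range(log.config.n_series):
        chunk = log.outcomes[s * n:(s + 1) * n]
        out.append(100.0 * sum(o.reached for o in chunk) / len(chunk))
    return out


def trajectory_metrics(
    log: SessionLog, idle_speed_px_s: float = 10.0
) -> dict[str, float]:
    """Simple kinematic summaries of the airplane trajectory.

    Returns path length (px), mean time-to-hit over reached targets (s;
    NaN when nothing was reached) and the fraction of samples whose
    speed is below ``idle_speed_px_s``.
    """
    if not log.trajectory:
        raise ValueError("empty trajectory")
    arr = np.asarray(log.trajectory, dtype=float)
    d = np.diff(arr[:, 1:3], axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    dt = np.diff(arr[:, 0])
    speed = np.divide(seg, dt, out=np.zeros_like(seg), where=dt > 0)
    times = [o.time_to_hit for o in log.outcomes if o.reached]
    return {
        "path_length_px": float(seg.sum()),
        "mean_time_to_hit_s": float(np.mean(times)) if times else float("nan"),
        "idle_fraction": float(np.mean(speed < idle_speed_px_s)) if len(speed) else 1.0,
    }
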