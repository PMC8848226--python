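"""Target scheduling, hit detection, scoring and trajectory logging."""

import math

import numpy as np
import pytest

from cervigame import GameConfig, MappingConfig, generate_targets, run_session
from cervigame.engine import (TargetSpec, score_session, series_scores,
                              trajectory_metrics)
from cervigame.mapping import CursorPosition, angles_for_position


def grid_cursor(positions, duration, rate=50.0):
    """Cursor samples on a uniform grid; `positions` maps t -> (x, y)."""
    n = int(round(duration * rate)) + 1
    return [(k / rate, *positions(k / rate)) for k in range(n)]


class TestGenerateTargets:
    def test_protocol_schedule_has_42_specs_on_a_5s_cadence(self, game_config):
        specs = generate_targets(game_config, np.random.default_rng(0))
        assert len(specs) == 42
        assert [s.spawn_t for s in specs] == pytest.approx(
            [5.0 * k for k in range(42)]
        )
        assert specs[-1].spawn_t == 205.0
        assert all(s.deadline_t == s.spawn_t + 5.0 for s in specs)

    def test_same_seed_reproduces_sequence(self, game_config):
        a = generate_targets(game_config, np.random.default_rng(42))
        b = generate_targets(game_config, np.random.default_rng(42))
        assert [(t.position.x, t.position.y) for t in a] == [
            (t.position.x, t.position.y) for t in b
        ]

    def test_positions_stay_in_rom_box_with_min_separation(self):
        cfg = GameConfig(targets_per_series=10000, n_series=1, min_separation=5.0)
        specs = generate_targets(cfg, np.random.default_rng(1))
        m = cfg.mapping
        prev = None
        for s in specs:
            alpha, beta = angles_for_position(s.position, m)
            assert abs(alpha) <= cfg.required_rom + 1e-9
            assert abs(beta) <= cfg.required_rom + 1e-9
            if prev is not None:
                assert math.hypot(alpha - prev[0], beta - prev[1]) >= cfg.min_separation
            prev = (alpha, beta)

    def test_infeasible_separation_raises(self):
        cfg = GameConfig(required_rom=1.0, min_separation=10.0,
                         mapping=MappingConfig())
        with pytest.raises(RuntimeError, match="min_separation"):
            generate_targets(cfg, np.random.default_rng(0))


class TestRunSession:
    def test_perfect_tracker_scores_100(self, game_config):
        targets = generate_targets(game_config, np.random.default_rng(3))
        lookup = {k: targets[k].position for k in range(len(targets))}

        def track(t):
            k = min(int(t // 5.0), 41)
            return (lookup[k].x, lookup[k].y)

        log = run_session(game_config, grid_cursor(track, 210.0), targets=targets)
        assert log.score_percent == 100.0

    def test_frozen_cursor_scores_zero_on_off_center_targets(self, game_config):
        targets = [
            TargetSpec(k, CursorPosition(200.0, 150.0), 5.0 * k, 5.0 * k + 5.0)
            for k in range(42)
        ]
        log = run_session(game_config, grid_cursor(lambda t: (0.0, 0.0), 210.0),
                          targets=targets)
        assert log.score_percent == 0.0
        assert log.n_reached + log.n_missed == 42

    def test_seventeen_of_twentyone_gives_8095_percent(self):
        cfg = GameConfig(n_series=1)
        targets = [
            TargetSpec(k, CursorPosition(200.0, 100.0), 5.0 * k, 5.0 * k + 5.0)
            for k in range(21)
        ]

        def reach_first_17(t):
            return (200.0, 100.0) if t < 17 * 5.0 else (0.0, 0.0)

        log = run_session(cfg, grid_cursor(reach_first_17, 105.0), targets=targets)
        assert log.n_reached == 17
        assert log.score_percent == pytest.approx(100 * 17 / 21, abs=0.005)
        assert log.score_percent == pytest.approx(80.95, abs=0.005)

    def test_short_cursor_stream_raises(self, game_config):
        with pytest.raises(ValueError, match="lasts 210"):
            run_session(game_config, grid_cursor(lambda t: (0, 0), 100.0),
                        rng=np.random.default_rng(0))

    def test_replaying_logged_trajectory_reproduces_outcomes(self, game_config):
        targets = generate_targets(game_config, np.random.default_rng(9))
        rng = np.random.default_rng(10)
        wander = grid_cursor(
            lambda t: (float(300 * math.sin(t / 7)), float(200 * math.cos(t / 5))),
            210.0,
        )
        log1 = run_session(game_config, wander, targets=targets)
        log2 = run_session(game_config, log1.trajectory, targets=targets)
        assert log1.outcomes == log2.outcomes
        assert log1.trajectory == log2.trajectory

    def test_conservation_reached_plus_missed(self, game_config):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            targets = generate_targets(game_config, rng)
            log = run_session(
                game_config,
                grid_cursor(lambda t: (float(np.sin(t) * 400), float(np.cos(t) * 250)),
                            210.0),
                targets=targets,
            )
            assert log.n_reached + log.n_missed == game_config.total_targets

    def test_session_duration_matches_protocol(self, game_config):
        assert game_config.session_duration_s == 210.0
        assert game_config.total_targets == 42


class TestScoring:
    @pytest.mark.parametrize("reached,expected", [(42, 100.0), (0, 0.0), (29, 69.05)])
    def test_score_arithmetic(self, game_config, reached, expected):
        targets = [
            TargetSpec(k, CursorPosition(300.0, 200.0), 5.0 * k, 5.0 * k + 5)
            for k in range(42)
        ]

        def cursor(t):
            return (300.0, 200.0) if t < reached * 5.0 else (0.0, 0.0)

        log = run_session(game_config, grid_cursor(cursor, 210.0), targets=targets)
        assert log.n_reached == reached
        assert score_session(log) == pytest.approx(expected, abs=0.005)

    def test_day_score_is_mean_of_series(self, game_config):
        targets = [
            TargetSpec(k, CursorPosition(300.0, 200.0), 5.0 * k, 5.0 * k + 5)
            for k in range(42)
        ]
        # reach all of series 1, none of series 2
        log = run_session(
            game_config,
            grid_cursor(lambda t: (300.0, 200.0) if t < 105 else (0.0, 0.0), 210.0),
            targets=targets,
        )
        assert series_scores(log) == [100.0, 0.0]
        assert score_session(log) == pytest.approx(np.mean(series_scores(log)))


class TestTrajectoryMetrics:
    def test_stationary_trajectory_has_zero_path_length(self, game_config):
        targets = [TargetSpec(0, CursorPosition(300, 200), 0.0, 5.0)]
        cfg = GameConfig(targets_per_series=1, n_series=1)
        log = run_session(cfg, grid_cursor(lambda t: (0.0, 0.0), 5.0), targets=targets)
        assert trajectory_metrics(log)["path_length_px"] == 0.0
        assert trajectory_metrics(log)["idle_fraction"] == 1.0

    def test_square_path_length(self):
        cfg = GameConfig(targets_per_series=1, n_series=1, inter_target_s=4.0)
        targets = [TargetSpec(0, CursorPosition(300, 200), 0.0, 4.0)]
        corners = [(0, 0), (100, 0), (100, 100), (0, 100), (0, 0)]
        traj = [(float(i), *map(float, corners[i])) for i in range(5)]
        log = run_session(cfg, traj, targets=targets)
        assert trajectory_metrics(log)["path_length_px"] == pytest.approx(400.0)

    def test_matches_independent_recomputation(self, game_config, rng):
        targets = generate_targets(game_config, rng)
        traj = grid_cursor(
            lambda t: (float(np.sin(0.3 * t) * 350), float(np.cos(0.2 * t) * 250)),
            210.0,
        )
        log = run_session(game_config, traj, targets=targets)
        m = trajectory_metrics(log)
        arr = np.array(log.trajectory)
        path = float(np.sum(np.linalg.norm(np.diff(arr[:, 1:], axis=0), axis=1)))
        assert m["path_length_px"] == pytest.approx(path, rel=1e-12)
        hits = [o.time_to_hit for o in log.outcomes if o.reached]
        if hits:
            assert m["mean_time_to_hit_s"] == pytest.approx(float(np.mean(hits)))
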