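"""Crossover-trial statistics: paired tests, design effects, RM-ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cervigame.trial_stats import (ALPHA, CrossoverDataset, normality_gate,
                                   paired_t, period_effect, residual_effect,
                                   rm_anova_sessions, sequence_effect,
                                   simulate_crossover_dataset,
                                   wilcoxon_by_group, wilcoxon_signed_rank)


def rm_anova_bruteforce(X):
    """From-scratch sums-of-squares over explicit loops (independent oracle)."""
    X = np.asarray(X, float)
    n, k = X.shape
    grand = sum(X[i][j] for i in range(n) for j in range(k)) / (n * k)
    col_means = [sum(X[i][j] for i in range(n)) / n for j in range(k)]
    row_means = [sum(X[i][j] for j in range(k)) / k for i in range(n)]
    ss_sessions = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_error = sum(
        (X[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    df1, df2 = k - 1, (n - 1) * (k - 1)
    return (ss_sessions / df1) / (ss_error / df2)


class TestPairedT:
    def test_identical_samples_degenerate_no_effect(self):
        res = paired_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_closed_form_arithmetic(self):
        # differences (1, 2, 3): t = 2 / (1/sqrt(3))
        res = paired_t([2, 4, 6], [1, 2, 3])
        assert res.statistic == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-9)
        assert res.statistic == pytest.approx(3.464, abs=0.001)
        assert res.p_value == pytest.approx(0.0742, abs=0.0005)
        assert res.effect == pytest.approx(2.0)

    def test_constant_nonzero_difference_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([2, 3, 4], [1, 2, 3])

    @pytest.mark.parametrize("x,y", [([1], [2]), ([1, 2], [1, 2, 3])])
    def test_bad_shapes_rejected(self, x, y):
        with pytest.raises(ValueError):
            paired_t(x, y)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            paired_t(rng.normal(size=13), rng.normal(size=13)).p_value < ALPHA
            for _ in range(400)
        )
        assert 0.02 < rejections / 400 < 0.08


class TestWilcoxon:
    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0
        assert "degenerate" in res.extra

    def test_positive_rank_sum_by_hand_enumeration(self):
        # differences (1, -2, 3, -4, 5): |d| ranks 1..5, positive ranks 1+3+5
        res = wilcoxon_signed_rank([1, -2, 3, -4, 5], [0, 0, 0, 0, 0])
        assert res.extra["w_plus"] == 9.0
        # exact p by full enumeration of the 2^5 sign assignments
        mags = [1, 2, 3, 4, 5]
        null = [sum(m for m, s in zip(mags, signs) if s > 0)
                for signs in itertools.product([-1, 1], repeat=5)]
        w = 9
        mean_w = 7.5
        p_exact = np.mean([abs(v - mean_w) >= abs(w - mean_w) for v in null])
        assert res.p_value == pytest.approx(p_exact, abs=1e-12)

    def test_shift_alternative_has_power_above_alpha(self):
        rng = np.random.default_rng(1)
        power = np.mean([
            wilcoxon_signed_rank(rng.normal(1.0, 1, 15), rng.normal(0, 1, 15)).p_value
            < ALPHA
            for _ in range(200)
        ])
        null_rate = np.mean([
            wilcoxon_signed_rank(rng.normal(size=15), rng.normal(size=15)).p_value
            < ALPHA
            for _ in range(200)
        ])
        assert power > 0.5 > null_rate + 0.2

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(2)
        res = wilcoxon_signed_rank(rng.normal(size=40), rng.normal(size=40))
        assert res.extra["method"] == "approx"


class TestCrossoverDataset:
    def test_missing_values_refused(self):
        df = simulate_crossover_dataset(8, np.random.default_rng(0)).df.copy()
        df.loc[0, "week8"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            CrossoverDataset(df)

    def test_unknown_sequence_refused(self):
        df = simulate_crossover_dataset(8, np.random.default_rng(0)).df.copy()
        df.loc[0, "sequence"] = "A-A"
        with pytest.raises(ValueError, match="sequence"):
            CrossoverDataset(df)

    def test_csv_round_trip(self, tmp_path):
        data = simulate_crossover_dataset(10, np.random.default_rng(3))
        p = tmp_path / "crossover.csv"
        data.df.to_csv(p, index=False)
        back = CrossoverDataset.from_csv(p)
        pd.testing.assert_frame_equal(back.df, data.df)


class TestResidualEffect:
    def test_null_rejects_at_nominal_rate(self):
        rng = np.random.default_rng(4)
        rate = np.mean([
            residual_effect(simulate_crossover_dataset(13, rng)).significant
            for _ in range(300)
        ])
        assert 0.01 < rate < 0.10

    def test_injected_carryover_detected_and_escalates(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 200
        for _ in range(reps):
            data = simulate_crossover_dataset(13, rng, carryover=-2.0)
            res = residual_effect(data)
            if res.significant:
                hits += 1
                assert set(res.extra["by_group"]) == {"A-B", "B-A"}
        assert hits / reps >= 0.8

    def test_single_subject_dataset_rejected(self):
        df = simulate_crossover_dataset(4, np.random.default_rng(0)).df.iloc[:1]
        with pytest.raises(ValueError):
            residual_effect(CrossoverDataset(df))


class TestPeriodEffect:
    def test_equal_periods_give_t_zero(self):
        data = simulate_crossover_dataset(10, np.random.default_rng(6))
        df = data.df.copy()
        df["week12"] = df["week4"]
        res = period_effect(CrossoverDataset(df))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_injected_period_shift_recovered(self):
        rng = np.random.default_rng(7)
        effs = [
            period_effect(
                simulate_crossover_dataset(
                    100, rng, effect_a=-1.5, effect_b=-1.5, period_shift=-1.0
                )
            ).effect
            for _ in range(100)
        ]
        # effect = mean(week4 - week12) = -period_shift
        assert np.mean(effs) == pytest.approx(1.0, abs=0.1)


class TestSequenceEffect:
    def test_identical_change_distributions_null_rate(self):
        rng = np.random.default_rng(8)
        rate = np.mean([
            sequence_effect(simulate_crossover_dataset(12, rng), "A").significant
            for _ in range(300)
        ])
        assert 0.01 < rate < 0.10

    def test_constructed_difference_detected(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(10):
            w0 = 5.0 + rng.normal(0, 0.1)
            rows.append({"subject": f"a{i}", "sequence": "A-B", "week0": w0,
                         "week4": w0 - 0.5 + rng.normal(0, 0.1),
                         "week8": w0, "week12": w0 - 0.7, "week16": w0})
        for i in range(10):
            w0 = 5.0 + rng.normal(0, 0.1)
            rows.append({"subject": f"b{i}", "sequence": "B-A", "week0": w0,
                         "week4": w0 - 0.7, "week8": w0,
                         "week12": w0 - 1.5 + rng.normal(0, 0.1), "week16": w0})
        res = sequence_effect(CrossoverDataset(pd.DataFrame(rows)), "A")
        assert res.extra["mean_change"]["B-A"] < res.extra["mean_change"]["A-B"]
        assert res.significant
        assert res.effect == pytest.approx(1.0, abs=0.15)

    def test_unknown_treatment_rejected(self):
        data = simulate_crossover_dataset(8, np.random.default_rng(0))
        with pytest.raises(ValueError, match="'A' or 'B'"):
            sequence_effect(data, "C")


class TestRmAnova:
    def test_constant_rows_give_f_zero(self):
        X = np.tile([[3.0], [5.0], [7.0]], (1, 4))
        res = rm_anova_sessions(X)
        assert res.statistic == 0.0

    def test_small_matrix_matches_bruteforce(self):
        X = np.array([[1.0, 2.0, 4.0], [2.0, 2.5, 5.0], [0.5, 1.0, 2.0]])
        res = rm_anova_sessions(X)
        assert res.statistic == pytest.approx(rm_anova_bruteforce(X), abs=1e-9)

    def test_all_5x5_random_fixtures_match_bruteforce(self):
        rng = np.random.default_rng(10)
        for n in range(2, 6):
            for k in range(2, 6):
                X = rng.normal(size=(n, k))
                assert rm_anova_sessions(X).statistic == pytest.approx(
                    rm_anova_bruteforce(X), abs=1e-9
                )

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        X = rng.normal(70, 10, size=(13, 8))
        res = rm_anova_sessions(X)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(13), 8),
            "session": np.tile(np.arange(8), 13),
            "score": X.ravel(),
        })
        ref = pg.rm_anova(data=long, dv="score", within="session", subject="subject")
        assert res.statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-6)

    def test_learning_data_yields_significant_session_effect(self, game_config):
        from cervigame.simulator import UserModel, simulate_protocol

        rng = np.random.default_rng(12)
        hits = 0
        reps = 5
        for r in range(reps):
            scores = np.array([
                simulate_protocol(UserModel(), game_config, 8,
                                  np.random.default_rng(1000 * r + s))
                for s in range(13)
            ])
            if rm_anova_sessions(scores).significant:
                hits += 1
        assert hits == reps

    def test_missing_cells_refused(self):
        X = np.ones((3, 3))
        X[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_sessions(X)


class TestNormalityGate:
    def test_gaussian_sample_usually_not_rejected(self):
        rng = np.random.default_rng(13)
        rate = np.mean([
            normality_gate(rng.normal(size=50)).p_value < ALPHA for _ in range(200)
        ])
        assert rate < 0.10

    def test_skewed_sample_rejected(self):
        rng = np.random.default_rng(14)
        res = normality_gate(rng.exponential(size=50))
        assert res.p_value < ALPHA

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="3"):
            normality_gate([1.0, 2.0])
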