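"""Gene-specific threshold search and default-vs-optimized comparison."""

import numpy as np
import pytest

from protovar.simulate import score_arrays_from_table, simulate_score_table
from protovar.threshold import (
    best_threshold_on,
    compare_default_vs_optimized,
    mcc_at_threshold,
    optimize_threshold,
    threshold_grid,
    undersample_balance,
)


def brute_best_threshold(scores, labels, grid):
    best_t, best_m = None, -np.inf
    for t in grid:
        m = mcc_at_threshold(scores, labels, t)
        if m > best_m:
            best_t, best_m = t, m
    return best_t, best_m


class TestGrid:
    def test_has_21_values(self):
        assert len(threshold_grid()) == 21

    def test_endpoints(self):
        grid = threshold_grid()
        assert grid[0] == 0.0 and grid[-1] == 1.0

    def test_uniform_spacing(self):
        np.testing.assert_allclose(np.diff(threshold_grid()), 0.05)


class TestBestThresholdOn:
    def test_separated_scores_lowest_qualifying_threshold(self):
        scores = np.r_[np.full(10, 0.9), np.full(10, 0.1)]
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        t, m = best_threshold_on(scores, labels)
        assert m == 1.0
        assert t == pytest.approx(0.15)  # lowest grid point above 0.1

    def test_equals_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        grid = threshold_grid()
        for _ in range(100):
            n = int(rng.integers(10, 60))
            scores = rng.uniform(size=n)
            labels = rng.integers(0, 2, size=n)
            if len(set(labels)) < 2:
                labels[0] = 1 - labels[0]
            t, m = best_threshold_on(scores, labels, grid)
            bt, bm = brute_best_threshold(scores, labels, grid)
            assert t == bt and m == bm

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            best_threshold_on([0.1, 0.9], [1, 1])


class TestOptimizeThreshold:
    def test_recovers_symmetric_beta_crossing(self):
        recovered = []
        for seed in range(20):
            table, labels, crossing = simulate_score_table(
                500, 500, (8, 2), (2, 8), seed=seed
            )
            scores, y = score_arrays_from_table(table, labels)
            res = optimize_threshold(scores, y, seed=seed)
            recovered.append(res.chosen_threshold)
        assert crossing == pytest.approx(0.5)
        assert abs(float(np.median(recovered)) - 0.5) <= 0.05

    def test_beats_miscalibrated_default(self):
        wins = 0
        for seed in range(20):
            table, labels, _ = simulate_score_table(
                200, 200, (12, 4), (4, 12), seed=seed,
                default_threshold=0.9,
            )
            scores, y = score_arrays_from_table(table, labels)
            res = optimize_threshold(scores, y, default_threshold=0.9,
                                     seed=seed)
            wins += res.optimized_mcc > res.default_mcc
        assert wins >= 18

    def test_perfect_separation(self):
        scores = np.r_[np.full(30, 0.9), np.full(30, 0.1)]
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        res = optimize_threshold(scores, y, default_threshold=0.5, seed=0)
        assert res.optimized_mcc == 1.0
        assert res.default_mcc == 1.0  # 0.5 lies in the gap

    def test_shuffled_labels_no_optimism_leak(self):
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = rng.uniform(size=200)
            y = rng.permutation(np.r_[np.ones(100, int), np.zeros(100, int)])
            res = optimize_threshold(scores, y, seed=seed)
            means.append(res.optimized_mcc)
        assert abs(float(np.mean(means))) <= 0.1

    def test_train_threshold_distribution_narrows_with_n(self):
        sds = {}
        for n in (100, 2000):
            spreads = []
            for seed in range(20):
                table, labels, _ = simulate_score_table(
                    n // 2, n // 2, (6, 3), (3, 6), seed=seed
                )
                scores, y = score_arrays_from_table(table, labels)
                res = optimize_threshold(scores, y, seed=seed)
                spreads.append(np.std([t for t, _ in res.per_repeat]))
            sds[n] = float(np.mean(spreads))
        assert sds[2000] < sds[100]

    def test_per_repeat_has_repeats_times_k_entries(self):
        table, labels, _ = simulate_score_table(50, 50, seed=1)
        scores, y = score_arrays_from_table(table, labels)
        res = optimize_threshold(scores, y, repeats=10, k=5, seed=0)
        assert len(res.per_repeat) == 50
        assert res.chosen_threshold in res.grid

    def test_too_few_per_class_errors(self):
        with pytest.raises(ValueError):
            optimize_threshold([0.1, 0.9, 0.5], [0, 1, 1], k=5)


class TestUndersample:
    def test_sizes_forced(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=130)
        y = np.r_[np.ones(30, int), np.zeros(100, int)]
        s2, y2 = undersample_balance(scores, y, seed=0)
        assert (y2 == 1).sum() == (y2 == 0).sum() == 30

    def test_balanced_input_unchanged(self):
        scores = np.linspace(0, 1, 20)
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        s2, y2 = undersample_balance(scores, y, seed=0)
        np.testing.assert_array_equal(s2, scores)

    def test_subset_without_replacement(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=80)
        y = np.r_[np.ones(20, int), np.zeros(60, int)]
        s2, y2 = undersample_balance(scores, y, seed=3)
        counts = {}
        for v in s2:
            counts[v] = counts.get(v, 0) + 1
        assert all(c == 1 for c in counts.values())
        assert set(s2) <= set(scores)

    def test_balanced_mode_shifts_threshold_up(self):
        # a pathogenic-dominated cohort (high scores in the majority)
        # drags the imbalanced-mode threshold down; undersampling the
        # majority moves the chosen threshold back up
        imb, bal = [], []
        for seed in range(10):
            table, labels, _ = simulate_score_table(
                400, 40, (6, 3), (2, 6), seed=seed
            )
            scores, y = score_arrays_from_table(table, labels)
            imb.append(optimize_threshold(scores, y, seed=seed).chosen_threshold)
            s2, y2 = undersample_balance(scores, y, seed)
            bal.append(optimize_threshold(s2, y2, seed=seed).chosen_threshold)
        assert np.mean(bal) > np.mean(imb)


class TestCompare:
    def _tables(self, seed, miscalibrated):
        """Five genes; miscalibrated ones have optimum far from 0.5."""
        out = {}
        for g in range(5):
            if g < miscalibrated:
                betas = ((14, 3), (10, 10))  # densities cross near 0.68
            else:
                betas = ((8, 2), (2, 8))     # cross at 0.5 (calibrated)
            table, labels, _ = simulate_score_table(
                80, 80, *betas, seed=seed * 13 + g, gene_id=f"G{g}"
            )
            scores, y = score_arrays_from_table(table, labels)
            out[f"G{g}"] = (scores, y, 0.5)
        return out

    def test_improvement_count_matches_miscalibration(self):
        hits = 0
        for seed in range(20):
            _, improved = compare_default_vs_optimized(
                self._tables(seed, miscalibrated=3), seed=seed
            )
            hits += improved >= 3
        assert hits >= 18

    def test_calibrated_panel_no_systematic_improvement(self):
        # held-out MCC at the trained threshold should match the
        # (already optimal) default on average: improvements are coin
        # flips, not a systematic gain
        counts, deltas = [], []
        for seed in range(10):
            results, improved = compare_default_vs_optimized(
                self._tables(seed, miscalibrated=0), seed=seed
            )
            counts.append(improved)
            deltas += [r.optimized_mcc - r.default_mcc for r in results]
        assert abs(float(np.mean(deltas))) < 0.02
        assert 0.0 <= np.mean(counts) <= 3.5

    def test_single_gene_count_in_range(self):
        _, improved = compare_default_vs_optimized(
            self._tables(0, miscalibrated=1), seed=0
        )
        assert improved in range(0, 6)
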