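"""Metrics, cross-validation semantics, selection and statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import protovar as pv
from protovar.datamodel import WeightedDataset
from protovar.evaluate import (
    ConfusionCounts,
    _FoldCache,
    correlation_rank,
    kruskal_wallis,
    mcc,
    mcc_from_predictions,
    pr_auc,
    repeated_kfold_cv,
    roc_auc,
    select_algorithm,
    select_features,
    wilcoxon_signed_rank,
)
from protovar.pipeline import GenePipeline


def brute_roc_auc(scores, labels):
    """All-pairs Mann-Whitney counting."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def brute_average_precision(scores, labels):
    """Descending sweep; ties grouped; precision accumulated at each
    recall step (the average-precision convention)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    out = 0.0
    prev_recall = 0.0
    n_pos = labels.sum()
    for t in sorted(set(scores), reverse=True):
        sel = scores >= t
        tp = int(labels[sel].sum())
        precision = tp / sel.sum()
        recall = tp / n_pos
        out += precision * (recall - prev_recall)
        prev_recall = recall
    return out


class TestMCC:
    def test_perfect_prediction(self):
        assert mcc(ConfusionCounts(tp=10, tn=10, fp=0, fn=0)) == 1.0

    def test_degenerate_margin_is_zero(self):
        assert mcc(ConfusionCounts(tp=10, fp=5, tn=0, fn=0)) == 0.0

    def test_equals_pearson_phi(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            y = rng.integers(0, 2, size=30)
            p = rng.integers(0, 2, size=30)
            if len(set(y)) < 2 or len(set(p)) < 2:
                continue
            phi = np.corrcoef(y, p)[0, 1]
            assert mcc_from_predictions(y, p) == pytest.approx(phi, abs=1e-12)

    def test_symmetries(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=40)
        p = rng.integers(0, 2, size=40)
        m = mcc_from_predictions(y, p)
        assert mcc_from_predictions(1 - y, 1 - p) == pytest.approx(m, abs=1e-12)
        assert mcc_from_predictions(y, 1 - p) == pytest.approx(-m, abs=1e-12)


class TestROCAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0.5] * 10, [1] * 5 + [0] * 5) == 0.5

    def test_matches_pair_counting(self):
        rng = np.random.default_rng(2)
        scores = rng.choice(np.linspace(0, 1, 7), size=15)
        labels = np.r_[np.ones(8, int), np.zeros(7, int)]
        assert roc_auc(scores, labels) == pytest.approx(
            brute_roc_auc(scores, labels), abs=1e-12
        )

    def test_flip_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30)
        if len(set(labels)) < 2:
            labels[0] = 1 - labels[0]
        assert roc_auc(1 - scores, 1 - labels) == pytest.approx(
            roc_auc(scores, labels), abs=1e-12
        )

    def test_random_scores_centre_on_half(self):
        rng = np.random.default_rng(4)
        aucs = [
            roc_auc(rng.uniform(size=200),
                    np.r_[np.ones(100, int), np.zeros(100, int)])
            for _ in range(100)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestPRAUC:
    def test_perfect_separation(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_worst(self):
        scores = np.linspace(1.0, 0.1, 10)
        labels = np.zeros(10, int)
        labels[-1] = 1  # the positive has the lowest score
        assert pr_auc(scores, labels) == pytest.approx(0.1)

    def test_matches_brute_force_sweep(self):
        rng = np.random.default_rng(5)
        scores = rng.choice(np.linspace(0, 1, 6), size=15)
        labels = rng.integers(0, 2, size=15)
        labels[0] = 1
        assert pr_auc(scores, labels) == pytest.approx(
            brute_average_precision(scores, labels), abs=1e-12
        )

    def test_no_positives_errors(self):
        with pytest.raises(ValueError):
            pr_auc([0.1, 0.2], [0, 0])


class _ScriptedPipeline:
    """Predicts a fixed score per instance id (first feature column)."""

    algorithm_id = "scripted"

    def __init__(self, score_by_id):
        self.score_by_id = score_by_id

    def fit(self, dataset):
        return self

    def predict_proba(self, X):
        return np.array([self.score_by_id[int(i)] for i in X[:, 0]])


class TestRepeatedKFoldCV:
    def test_pooled_confusion_not_fold_average(self):
        # Construct predictions whose pooled MCC differs from the mean
        # of per-fold MCCs: correct in some folds, inverted in others.
        n = 40
        y = np.array([1, 0] * (n // 2))
        ids = np.arange(n, dtype=float)
        scripted = {int(i): (0.9 if ((i // 4) % 2 == 0) == (y[i] == 1) else 0.1)
                    for i in range(n)}
        ds = WeightedDataset(ids[:, None], y, np.ones(n), ["id"])
        report = repeated_kfold_cv(
            ds, lambda s: _ScriptedPipeline(scripted), k=4, repeats=1, seed=0
        )
        pooled_pred = (np.array([scripted[i] for i in range(n)]) >= 0.5)
        expected = mcc_from_predictions(y, pooled_pred.astype(int))
        assert report.per_repeat_mcc[0] == pytest.approx(expected, abs=1e-12)

    def test_deterministic_given_seed(self, small_dataset):
        f = lambda s: GenePipeline(algorithm_id="logitboost", seed=s)
        a = repeated_kfold_cv(small_dataset, f, k=5, repeats=2, seed=9)
        b = repeated_kfold_cv(small_dataset, f, k=5, repeats=2, seed=9)
        assert a.per_repeat_mcc == b.per_repeat_mcc
        assert a.mcc_sd == b.mcc_sd

    def test_majority_predictor_scores_zero(self):
        n = 100
        y = np.r_[np.ones(30, int), np.zeros(70, int)]
        ids = np.arange(n, dtype=float)
        scripted = {i: 0.0 for i in range(n)}  # always predict benign
        ds = WeightedDataset(ids[:, None], y, np.ones(n), ["id"])
        report = repeated_kfold_cv(
            ds, lambda s: _ScriptedPipeline(scripted), k=5, repeats=3, seed=1
        )
        assert report.mcc_mean == 0.0 and report.mcc_sd == 0.0

    def test_small_class_reduces_k(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 2))
        y = np.r_[np.ones(5, int), np.zeros(25, int)]
        ds = WeightedDataset(X, y, np.ones(30))
        with pytest.warns(UserWarning, match="reducing k"):
            report = repeated_kfold_cv(
                ds, lambda s: GenePipeline("logitboost", seed=s),
                k=10, repeats=1, seed=0,
            )
        assert report.k == 5

    def test_fold_cache_equals_full_pipeline(self, small_dataset):
        report = repeated_kfold_cv(
            small_dataset,
            lambda s: GenePipeline(algorithm_id="logitboost", seed=s),
            k=10, repeats=2, seed=3,
        )
        cached = _FoldCache(small_dataset, k=10, repeats=2, seed=3)
        assert cached.cv_report("logitboost").per_repeat_mcc == pytest.approx(
            report.per_repeat_mcc, abs=1e-12
        )


class TestCorrelationRank:
    def test_label_copy_ranks_first(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, size=50)
        X = np.column_stack([rng.normal(size=50), y.astype(float),
                             np.ones(50)])
        ranked = correlation_rank(X, y, ["noise", "copy", "const"])
        assert ranked[0] == ("copy", pytest.approx(1.0))
        assert dict(ranked)["const"] == 0.0

    def test_matches_direct_computation(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 5))
        y = rng.integers(0, 2, size=40)
        ranked = dict(correlation_rank(X, y))
        for j in range(5):
            expected = abs(np.corrcoef(X[:, j], y)[0, 1])
            assert ranked[f"f{j}"] == pytest.approx(expected, abs=1e-12)


class TestFeatureSelection:
    def _signal_dataset(self, seed, n=150):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        informative = [
            y + rng.normal(0, 0.35, n),
            y + rng.normal(0, 0.5, n),
            -y + rng.normal(0, 0.5, n),
        ]
        noise = [rng.normal(size=n) for _ in range(5)]
        X = np.column_stack(informative + noise)
        names = [f"inf{j}" for j in range(3)] + [f"noise{j}" for j in range(5)]
        # selection requires catalogue names; rename via generic numerics
        return WeightedDataset(X, y, np.ones(n), names)

    def test_noise_features_eliminated(self):
        hits = 0
        for seed in range(10):
            ds = self._signal_dataset(seed)
            selected, _ = select_features(ds, "logitboost", seed=seed, k=5)
            if not any(n.startswith("noise") for n in selected):
                hits += 1
        assert hits >= 8

    def test_duplicate_features_collapse_to_one(self):
        rng = np.random.default_rng(14)
        y = np.r_[np.ones(60, int), np.zeros(60, int)]
        col = y + rng.normal(0, 0.3, 120)
        X = np.column_stack([col] * 4)
        ds = WeightedDataset(X, y, np.ones(120),
                             [f"copy{j}" for j in range(4)])
        selected, _ = select_features(ds, "logitboost", seed=0, k=5)
        assert len(selected) == 1

    def test_deterministic(self):
        ds = self._signal_dataset(99)
        a, _ = select_features(ds, "logitboost", seed=5, k=5)
        b, _ = select_features(ds, "logitboost", seed=5, k=5)
        assert a == b


class TestAlgorithmSelection:
    def test_linear_signal_beats_majority(self, small_dataset):
        algo, reports = select_algorithm(small_dataset, seed=0, k=5, repeats=2)
        assert algo in ("logitboost", "simple_logistic")
        assert reports[algo].mcc_mean > 0.5

    def test_tie_breaks_by_precedence(self):
        X = np.ones((40, 2))
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        ds = WeightedDataset(X, y, np.ones(40))
        algo, reports = select_algorithm(ds, seed=0, k=5, repeats=2)
        assert algo == "logitboost"  # all MCCs are 0; precedence decides
        assert all(r.mcc_mean == 0.0 for r in reports.values())

    def test_reported_mcc_is_the_winners(self, small_dataset):
        algo, reports = select_algorithm(small_dataset, seed=1, k=5, repeats=2)
        assert reports[algo].mcc_mean == max(r.mcc_mean for r in reports.values())


class TestKruskalWallis:
    def test_identical_groups(self):
        assert kruskal_wallis([[1, 1, 1], [1, 1, 1], [1, 1, 1]]) == (0.0, 1.0)

    def test_hand_ranked_example(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        # ranks 1..9, group rank sums 6, 15, 24:
        # H = 12/(9*10) * (36+225+576)/3 - 3*10 = 7.2
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(1 - sps.chi2.cdf(7.2, df=2))

    def test_permutation_p_matches_chi_square(self):
        rng = np.random.default_rng(15)
        groups = [rng.normal(size=15), rng.normal(0.5, 1, size=15),
                  rng.normal(1.0, 1, size=15)]
        h_obs, p_chi2 = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            h, _ = kruskal_wallis([pooled[:15], pooled[15:30], pooled[30:]])
            count += h >= h_obs
        assert abs(count / n_perm - p_chi2) < 0.03


class TestWilcoxon:
    def test_identical_pairs(self):
        a = np.arange(10, dtype=float)
        assert wilcoxon_signed_rank(a, a) == (0.0, 1.0)

    def test_exact_small_sample_enumeration(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = np.array([0.5, 2.3, 2.1, 3.0, 4.1, 4.8])
        d = a - b
        w_obs, p_obs = wilcoxon_signed_rank(a, b)
        ranks = sps.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        w_minus = ranks[d < 0].sum()
        assert w_obs == min(w_plus, w_minus)
        # enumerate all 2^6 sign assignments for the exact two-sided p
        stats = []
        for signs in itertools.product([1, -1], repeat=6):
            wp = sum(r for r, s in zip(ranks, signs) if s > 0)
            stats.append(min(wp, ranks.sum() - wp))
        p_exact = np.mean([s <= w_obs for s in stats])
        assert p_obs == pytest.approx(p_exact, abs=1e-12)

    def test_type_one_error_controlled(self):
        rng = np.random.default_rng(16)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            d = rng.normal(size=20)
            _, p = wilcoxon_signed_rank(d, np.zeros(20))
            rejections += p < 0.05
        assert rejections / n_sim <= 0.07
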