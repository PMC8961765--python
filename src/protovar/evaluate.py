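"""Metrics, cross-validation, feature/algorithm selection and statistics.

The Matthews correlation coefficient is the primary model-selection
metric throughout; ROC AUC and PR AUC summarize threshold-free
performance; repeated stratified k-fold cross-validation with random
subsampling provides the mean-and-SD reports; a correlation-guided
backward elimination retains the minimal feature set that preserves the
highest MCC; Kruskal–Wallis and Wilcoxon signed-rank tests support
between-tool comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datamodel import WeightedDataset
from .pipeline import GenePipeline

ALGORITHM_PRECEDENCE = ("logitboost", "simple_logistic", "hoeffding_tree")


@dataclass
class ConfusionCounts:
    """Weighted confusion-matrix counts."""

    tp: float = 0.0
    fp: float = 0.0
    tn: float = 0.0
    fn: float = 0.0

    @classmethod
    def from_predictions(cls, y_true, y_pred, w=None) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        w = np.ones(len(y_true)) if w is None else np.asarray(w, float)
        return cls(
            tp=float(w[(y_true == 1) & (y_pred == 1)].sum()),
            fp=float(w[(y_true == 0) & (y_pred == 1)].sum()),
            tn=float(w[(y_true == 0) & (y_pred == 0)].sum()),
            fn=float(w[(y_true == 1) & (y_pred == 0)].sum()),
        )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom <= 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def mcc_from_predictions(y_true, y_pred) -> float:
    return mcc(ConfusionCounts.from_predictions(y_true, y_pred))


def roc_auc(scores, labels) -> float:
    """ROC AUC = P(score_pos > score_neg) + 0.5 P(tie) over all pairs."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores, labels) -> float:
    """Area under the precision–recall curve (average-precision convention)."""
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("PR AUC needs at least one positive instance")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class EvalReport:
    """Mean-and-SD summary of a repeated cross-validation run."""

    algorithm_id: str
    features_used: list[str]
    mcc_mean: float
    mcc_sd: float
    roc_auc_mean: float
    roc_auc_sd: float
    pr_auc_mean: float
    pr_auc_sd: float
    per_repeat_mcc: list[float] = field(default_factory=list)
    k: int = 10
    repeats: int = 10

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm_id,
            "features_used": list(self.features_used),
            "n_features": len(self.features_used),
            "mcc_mean": self.mcc_mean,
            "mcc_sd": self.mcc_sd,
            "roc_auc_mean": self.roc_auc_mean,
            "roc_auc_sd": self.roc_auc_sd,
            "pr_auc_mean": self.pr_auc_mean,
            "pr_auc_sd": self.pr_auc_sd,
            "per_repeat_mcc": list(self.per_repeat_mcc),
            "k": self.k,
            "repeats": self.repeats,
        }


def repeated_kfold_cv(
    dataset: WeightedDataset,
    make_pipeline,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """Repeated stratified k-fold CV with a fresh shuffle per repeat.

    ``make_pipeline(seed)`` must return an unfitted pipeline exposing
    ``fit(WeightedDataset)`` and ``predict_proba(X)``. Preprocessing
    lives inside the pipeline, so it is refitted on every training
    fold. Per repeat, fold predictions are pooled into one confusion
    matrix (and one score vector); the report gives mean and SD across
    repeats. ``k`` is reduced with a warning when a class is smaller
    than ``k``.
    """
    y = dataset.y
    min_class = int(min(np.sum(y == 1), np.sum(y == 0)))
    if min_class < 2:
        raise ValueError("need at least 2 instances per class for CV")
    k_eff = min(k, min_class)
    if k_eff < k:
        warnings.warn(
            f"reducing k from {k} to {k_eff}: smallest class has "
            f"{min_class} instances", stacklevel=2,
        )

    mccs, rocs, prs = [], [], []
    for r in range(repeats):
        splitter = StratifiedKFold(
            n_splits=k_eff, shuffle=True, random_state=(seed * 1009 + r) % (2**31)
        )
        pooled_true = np.empty(len(y), dtype=int)
        pooled_score = np.empty(len(y), dtype=float)
        pos = 0
        for train_idx, test_idx in splitter.split(dataset.X, y):
            pipe = make_pipeline((seed * 1009 + r) % (2**31))
            pipe.fit(dataset.subset(train_idx))
            scores = pipe.predict_proba(dataset.X[test_idx])
            n_te = len(test_idx)
            pooled_true[pos:pos + n_te] = y[test_idx]
            pooled_score[pos:pos + n_te] = scores
            pos += n_te
        pred = (pooled_score >= threshold).astype(int)
        mccs.append(mcc_from_predictions(pooled_true, pred))
        rocs.append(roc_auc(pooled_score, pooled_true))
        prs.append(pr_auc(pooled_score, pooled_true))

    return EvalReport(
        algorithm_id=getattr(make_pipeline(0), "algorithm_id", "pipeline"),
        features_used=list(dataset.feature_names),
        mcc_mean=float(np.mean(mccs)),
        mcc_sd=float(np.std(mccs, ddof=1)) if repeats > 1 else 0.0,
        roc_auc_mean=float(np.mean(rocs)),
        roc_auc_sd=float(np.std(rocs, ddof=1)) if repeats > 1 else 0.0,
        pr_auc_mean=float(np.mean(prs)),
        pr_auc_sd=float(np.std(prs, ddof=1)) if repeats > 1 else 0.0,
        per_repeat_mcc=[float(m) for m in mccs],
        k=k_eff,
        repeats=repeats,
    )


def correlation_rank(
    X: np.ndarray, y: np.ndarray, feature_names: list[str] | None = None
) -> list[tuple[str, float]]:
    """Features ordered by |Pearson correlation| with the class, descending.

    Missing values are pairwise-deleted; constant (or all-missing)
    features score 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    scored = []
    for j, name in enumerate(names):
        col = X[:, j]
        mask = ~np.isnan(col)
        score = 0.0
        if mask.sum() >= 2:
            xv, yv = col[mask], y[mask]
            if np.std(xv) > 0 and np.std(yv) > 0:
                score = abs(float(np.corrcoef(xv, yv)[0, 1]))
        scored.append((name, score))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


class _FoldCache:
    """Precomputed per-fold preprocessing for the selection loops.

    Class balancing is feature-independent and MDL cut points are
    per-column, so folds can be preprocessed once and reused across
    candidate feature subsets and algorithms; results are identical to
    running the full pipeline per fold (asserted in the test suite).
    """

    def __init__(self, dataset: WeightedDataset, k: int, repeats: int,
                 seed: int):
        from .preprocess import apply_discretization, class_balance, \
            fit_discretization
        from .pipeline import GenePipeline

        self.dataset = dataset
        self.names = list(dataset.feature_names)
        self.k = k
        self.repeats = repeats
        self.seed = seed
        proto = GenePipeline()
        self.numeric = proto._numeric_in(self.names)
        self.categorical = proto._categorical_in(self.names)
        self.folds = []  # (train_idx, test_idx, Xtr_disc, Xte_disc, w_bal, fold_seed)
        y = dataset.y
        min_class = int(min(np.sum(y == 1), np.sum(y == 0)))
        k_eff = min(k, min_class)
        for r in range(repeats):
            fold_seed = (seed * 1009 + r) % (2**31)
            splitter = StratifiedKFold(n_splits=k_eff, shuffle=True,
                                       random_state=fold_seed)
            for train_idx, test_idx in splitter.split(dataset.X, y):
                train = class_balance(dataset.subset(train_idx))
                dmap = fit_discretization(train, self.numeric)
                Xtr = apply_discretization(dmap, train.X, self.names)
                Xte = apply_discretization(dmap, dataset.X[test_idx],
                                           self.names)
                self.folds.append(
                    (train_idx, test_idx, Xtr, Xte, train.w, fold_seed, r)
                )

    def cv_report(self, algorithm_id: str,
                  keep: list[str] | None = None) -> EvalReport:
        """Full pooled-per-repeat report for one algorithm/feature subset."""
        from .classify import make_classifier

        keep = keep if keep is not None else self.names
        cols = [self.names.index(n) for n in keep]
        categorical = ({n for n in keep if n in self.categorical}
                       | {n for n in keep if n in self.numeric})
        y = self.dataset.y
        per_repeat: dict[int, list] = {}
        for train_idx, test_idx, Xtr, Xte, w_bal, fold_seed, r in self.folds:
            clf = make_classifier(algorithm_id, seed=fold_seed,
                                  categorical=categorical)
            clf.fit(WeightedDataset(Xtr[:, cols], y[train_idx], w_bal,
                                    list(keep)))
            scores = clf.predict_proba(Xte[:, cols])
            per_repeat.setdefault(r, []).append((y[test_idx], scores))
        mccs, rocs, prs = [], [], []
        for r in sorted(per_repeat):
            chunks = per_repeat[r]
            truth = np.concatenate([t for t, _ in chunks])
            pooled = np.concatenate([s for _, s in chunks])
            mccs.append(mcc_from_predictions(truth, (pooled >= 0.5).astype(int)))
            rocs.append(roc_auc(pooled, truth))
            prs.append(pr_auc(pooled, truth))
        n_rep = len(mccs)
        return EvalReport(
            algorithm_id=algorithm_id,
            features_used=list(keep),
            mcc_mean=float(np.mean(mccs)),
            mcc_sd=float(np.std(mccs, ddof=1)) if n_rep > 1 else 0.0,
            roc_auc_mean=float(np.mean(rocs)),
            roc_auc_sd=float(np.std(rocs, ddof=1)) if n_rep > 1 else 0.0,
            pr_auc_mean=float(np.mean(prs)),
            pr_auc_sd=float(np.std(prs, ddof=1)) if n_rep > 1 else 0.0,
            per_repeat_mcc=[float(m) for m in mccs],
            k=self.k,
            repeats=n_rep,
        )

    def cv_mcc(self, algorithm_id: str, keep: list[str] | None = None) -> float:
        """Pooled-per-repeat mean CV MCC for one algorithm/feature subset."""
        return self.cv_report(algorithm_id, keep).mcc_mean


def _cv_mcc(dataset, algorithm_id, seed, repeats, k, **pipe_kwargs) -> float:
    report = repeated_kfold_cv(
        dataset,
        lambda s: GenePipeline(algorithm_id=algorithm_id, seed=s, **pipe_kwargs),
        k=k, repeats=repeats, seed=seed,
    )
    return report.mcc_mean


def select_features(
    dataset: WeightedDataset,
    algorithm_id: str,
    seed: int = 0,
    search_repeats: int = 3,
    k: int = 10,
    tolerance: float = 1e-9,
    max_passes: int = 3,
) -> tuple[list[str], dict]:
    """Minimal feature subset that maintains the highest CV MCC.

    Greedy backward elimination guided by the correlation ranking: the
    lowest-ranked remaining feature is tentatively dropped and the drop
    kept iff the cross-validated MCC does not decrease (beyond
    ``tolerance``). Passes repeat until no drop survives. At least one
    feature is always retained.
    """
    names = list(dataset.feature_names)
    ranked = correlation_rank(dataset.X, dataset.y, names)
    ascending = [name for name, _ in reversed(ranked)]
    cache = _FoldCache(dataset, k=k, repeats=search_repeats, seed=seed)

    current = list(names)
    best_mcc = cache.cv_mcc(algorithm_id, current)
    history = [("baseline", best_mcc, len(current))]
    for _ in range(max_passes):
        dropped_any = False
        for name in list(ascending):
            if name not in current or len(current) == 1:
                continue
            trial = [n for n in current if n != name]
            trial_mcc = cache.cv_mcc(algorithm_id, trial)
            if trial_mcc >= best_mcc - tolerance:
                current = trial
                best_mcc = max(best_mcc, trial_mcc)
                dropped_any = True
                history.append((f"drop {name}", trial_mcc, len(current)))
        if not dropped_any:
            break
    report = {
        "ranking": ranked,
        "history": history,
        "final_mcc": best_mcc,
        "selected": list(current),
    }
    return current, report


def select_algorithm(
    dataset: WeightedDataset,
    seed: int = 0,
    k: int = 10,
    repeats: int = 10,
) -> tuple[str, dict[str, EvalReport]]:
    """Pick the algorithm with the highest mean CV MCC.

    Ties resolve by fixed precedence (logitboost, then simple logistic,
    then Hoeffding tree).
    """
    cache = _FoldCache(dataset, k=k, repeats=repeats, seed=seed)
    reports: dict[str, EvalReport] = {}
    for algo in ALGORITHM_PRECEDENCE:
        reports[algo] = cache.cv_report(algo)
    best = max(
        ALGORITHM_PRECEDENCE,
        key=lambda a: (reports[a].mcc_mean, -ALGORITHM_PRECEDENCE.index(a)),
    )
    return best, reports


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; chi-square p on g−1 df."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the p-value is exact for n <= 25
    (tie-free) and a corrected normal approximation otherwise. All-zero
    differences give (0, 1).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 1.0
    if len(d) < 5:
        raise ValueError("need >= 5 non-zero differences")
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not has_ties) else "approx"
    w, p = sps.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                        method=method)
    return float(w), float(p)
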