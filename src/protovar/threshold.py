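"""Gene-specific pathogenicity thresholds for external predictor scores.

External tools ship a universal score cut-off (usually 0.5), but the
score distributions of pathogenic and benign variants differ between
genes. This module searches a fixed 21-point grid over [0, 1] for the
cut-off maximizing the Matthews correlation coefficient on 80% training
splits of a gene's scores (repeated n=10 fivefold cross-validation with
random subsampling) and reports the MCC obtained on the held-out 20%
at that threshold ("optimized" MCC), next to the MCC at the tool's
default threshold. An undersampling-balanced mode evaluates the same
procedure after the majority class is randomly subset to the minority
size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .datamodel import ScoreTable
from .evaluate import mcc_from_predictions


def threshold_grid(n: int = 21) -> np.ndarray:
    """The candidate thresholds: n evenly spaced values spanning [0, 1]."""
    return np.linspace(0.0, 1.0, n)


def mcc_at_threshold(scores, labels, threshold: float) -> float:
    """MCC of classifying pathogenic iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    return mcc_from_predictions(labels, (scores >= threshold).astype(int))


def best_threshold_on(scores, labels, grid=None) -> tuple[float, float]:
    """Grid threshold maximizing MCC; ties break toward the lowest value.

    Returns ``(threshold, mcc)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold search needs both classes present")
    grid = threshold_grid() if grid is None else np.asarray(grid, float)
    best_t, best_m = grid[0], -np.inf
    for t in grid:
        m = mcc_at_threshold(scores, labels, t)
        if m > best_m:  # strict: first (lowest) grid point wins ties
            best_t, best_m = t, m
    return float(best_t), float(best_m)


@dataclass
class ThresholdSearchResult:
    """Outcome of one gene/tool threshold optimization."""

    gene_id: str
    tool_name: str
    grid: list[float]
    chosen_threshold: float
    default_threshold: float
    default_mcc: float
    optimized_mcc: float
    per_repeat: list[tuple[float, float]] = field(default_factory=list)
    mode: str = "imbalanced"

    @property
    def improved(self) -> bool:
        return self.optimized_mcc > self.default_mcc

    def to_dict(self) -> dict:
        return {
            "gene": self.gene_id,
            "tool": self.tool_name,
            "mode": self.mode,
            "default_threshold": self.default_threshold,
            "default_mcc": self.default_mcc,
            "chosen_threshold": self.chosen_threshold,
            "optimized_mcc": self.optimized_mcc,
            "improved": self.improved,
        }


def _stratified_repeat(scores, labels, k, seed, max_retries=10):
    """Yield (train, test) index pairs; reshuffle on degenerate folds."""
    for retry in range(max_retries):
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=(seed + retry) % (2**31))
        folds = list(splitter.split(scores.reshape(-1, 1), labels))
        ok = all(
            len(np.unique(labels[tr])) == 2 and len(np.unique(labels[te])) == 2
            for tr, te in folds
        )
        if ok:
            return folds
    raise ValueError("could not produce two-class folds after retries")


def optimize_threshold(
    scores,
    labels,
    default_threshold: float = 0.5,
    repeats: int = 10,
    k: int = 5,
    seed: int = 0,
    grid=None,
    gene_id: str = "",
    tool_name: str = "",
    mode: str = "imbalanced",
) -> ThresholdSearchResult:
    """Repeated k-fold threshold search with held-out evaluation.

    Per repeat the data are shuffled and stratified into ``k`` folds;
    per fold the grid threshold maximizing MCC on the (k−1)/k training
    share is found and the MCC at that threshold measured on the
    held-out fold. The reported gene-specific threshold is the median
    of the repeats×k training thresholds, the optimized MCC the mean of
    the repeats×k held-out MCCs, and the default MCC the whole-data MCC
    at the tool's default threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if min(np.sum(labels == 1), np.sum(labels == 0)) < k:
        raise ValueError(f"need at least k={k} instances per class")
    grid = threshold_grid() if grid is None else np.asarray(grid, float)

    per_repeat: list[tuple[float, float]] = []
    for r in range(repeats):
        folds = _stratified_repeat(scores, labels, k, seed * 1013 + 7 * r)
        for train_idx, test_idx in folds:
            t, _ = best_threshold_on(scores[train_idx], labels[train_idx], grid)
            test_mcc = mcc_at_threshold(scores[test_idx], labels[test_idx], t)
            per_repeat.append((float(t), float(test_mcc)))

    train_thresholds = np.array([t for t, _ in per_repeat])
    test_mccs = np.array([m for _, m in per_repeat])
    return ThresholdSearchResult(
        gene_id=gene_id,
        tool_name=tool_name,
        grid=[float(g) for g in grid],
        chosen_threshold=float(np.median(train_thresholds)),
        default_threshold=float(default_threshold),
        default_mcc=mcc_at_threshold(scores, labels, default_threshold),
        optimized_mcc=float(np.mean(test_mccs)),
        per_repeat=per_repeat,
        mode=mode,
    )


def undersample_balance(scores, labels, seed: int = 0):
    """Balance classes by random majority undersampling (no replacement)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1, n0 = int(np.sum(labels == 1)), int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("undersampling needs both classes present")
    rng = np.random.default_rng(seed)
    if n1 == n0:
        return scores, labels
    minority, majority = (1, 0) if n1 < n0 else (0, 1)
    keep_major = rng.choice(
        np.flatnonzero(labels == majority), size=min(n1, n0), replace=False
    )
    idx = np.sort(np.concatenate([np.flatnonzero(labels == minority), keep_major]))
    return scores[idx], labels[idx]


def score_table_arrays(table: ScoreTable, variants) -> tuple[np.ndarray, np.ndarray]:
    """Align a score table with labelled variants -> (scores, labels).

    Variants without a score (or without a known label) are skipped.
    """
    scores, labels = [], []
    for v in variants:
        if v.label not in ("pathogenic", "benign"):
            continue
        s = table.score_of(v)
        if s is None:
            continue
        scores.append(s)
        labels.append(1 if v.label == "pathogenic" else 0)
    return np.asarray(scores, dtype=float), np.asarray(labels, dtype=int)


def compare_default_vs_optimized(
    gene_tables: dict[str, tuple[np.ndarray, np.ndarray, float]],
    mode: str = "imbalanced",
    repeats: int = 10,
    k: int = 5,
    seed: int = 0,
    tool_name: str = "",
) -> tuple[list[ThresholdSearchResult], int]:
    """Optimize every gene and count how many improved over the default.

    ``gene_tables`` maps gene id -> (scores, labels, default_threshold).
    In balanced mode each gene is undersampled (seeded per gene) before
    optimization.
    """
    results = []
    improved = 0
    for i, (gene, (scores, labels, default_t)) in enumerate(
        sorted(gene_tables.items())
    ):
        if mode == "balanced":
            scores, labels = undersample_balance(scores, labels, seed * 401 + i)
        res = optimize_threshold(
            scores, labels, default_threshold=default_t, repeats=repeats,
            k=k, seed=seed * 811 + i, gene_id=gene, tool_name=tool_name,
            mode=mode,
        )
        results.append(res)
        improved += int(res.improved)
    return results, improved
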