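"""Supervised instance filters applied before classifier training.

Two filters mirror the classic WEKA-style pipeline for imbalanced
per-gene variant data:

* **class balancing** — reweight the minority class so both classes
  carry the same total instance weight (each minority weight is
  multiplied by N_majority / N_minority; majority weights are left
  untouched);
* **supervised discretization** — Fayyad–Irani recursive binary
  splitting of numeric features on weighted class entropy, with the
  MDL stopping criterion.

Both operate on :class:`~protovar.datamodel.WeightedDataset` and are
meant to be fitted inside each cross-validation training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import WeightedDataset


def class_balance(dataset: WeightedDataset) -> WeightedDataset:
    """Reweight instances so both classes have equal total weight.

    The minority-class weights are multiplied by the class-size ratio;
    e.g. 20 pathogenic / 80 benign gives each pathogenic instance weight
    4 and a per-class total of 80. Balanced input is returned unchanged
    (all weights 1 stay 1).
    """
    y = dataset.y
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n0 == 0 or n1 == 0:
        raise ValueError("class balancing needs both classes present")
    w = dataset.w.astype(float).copy()
    if n1 < n0:
        w[y == 1] *= n0 / n1
    elif n0 < n1:
        w[y == 0] *= n1 / n0
    return WeightedDataset(dataset.X, y, w, list(dataset.feature_names))


def _entropy(class_weights: np.ndarray) -> float:
    """Shannon entropy (bits) of a weighted class distribution."""
    total = class_weights.sum()
    if total <= 0:
        return 0.0
    p = class_weights[class_weights > 0] / total
    return float(-(p * np.log2(p)).sum())


def _class_weight_vector(y, w) -> np.ndarray:
    return np.array([w[y == 0].sum(), w[y == 1].sum()])


def _mdl_accepts(y, w, left_mask) -> tuple[bool, float]:
    """Evaluate the MDL criterion for one binary split.

    Returns (accepted, information gain). ``N`` is the total instance
    weight; ``k`` counts the classes present in each partition.
    """
    right_mask = ~left_mask
    cw = _class_weight_vector(y, w)
    cw1 = _class_weight_vector(y[left_mask], w[left_mask])
    cw2 = _class_weight_vector(y[right_mask], w[right_mask])
    n = cw.sum()
    n1, n2 = cw1.sum(), cw2.sum()
    if n1 <= 0 or n2 <= 0:
        return False, 0.0
    ent, ent1, ent2 = _entropy(cw), _entropy(cw1), _entropy(cw2)
    gain = ent - (n1 / n) * ent1 - (n2 / n) * ent2
    k = int((cw > 0).sum())
    k1 = int((cw1 > 0).sum())
    k2 = int((cw2 > 0).sum())
    delta = np.log2(3.0**k - 2.0) - (k * ent - k1 * ent1 - k2 * ent2)
    threshold = (np.log2(max(n - 1.0, 1.0)) + delta) / n
    return gain > threshold, gain


def _entropy_rows(w0: np.ndarray, w1: np.ndarray) -> np.ndarray:
    """Vectorized two-class entropy for parallel (w0, w1) count pairs."""
    total = w0 + w1
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.where(total > 0, w0 / np.where(total > 0, total, 1.0), 0.0)
        p1 = np.where(total > 0, w1 / np.where(total > 0, total, 1.0), 0.0)
        h = -(np.where(p0 > 0, p0 * np.log2(np.where(p0 > 0, p0, 1.0)), 0.0)
              + np.where(p1 > 0, p1 * np.log2(np.where(p1 > 0, p1, 1.0)), 0.0))
    return h


def _best_cut(x, y, w):
    """Best boundary cut point of one numeric column, or None.

    Candidate cuts are midpoints between adjacent distinct values; the
    cut maximizing weighted information gain is accepted only if it
    passes the MDL test. The sweep is vectorized over all candidates.
    """
    order = np.argsort(x, kind="mergesort")
    xs, ys, ws = x[order], y[order], w[order]
    boundaries = np.flatnonzero(np.diff(xs) > 0)  # last index of each run
    if len(boundaries) == 0:
        return None
    cw0 = np.cumsum(ws * (ys == 0))
    cw1 = np.cumsum(ws * (ys == 1))
    l0, l1 = cw0[boundaries], cw1[boundaries]
    t0, t1 = cw0[-1], cw1[-1]
    r0, r1 = t0 - l0, t1 - l1
    n = t0 + t1
    n1, n2 = l0 + l1, r0 + r1
    ent = _entropy_rows(np.array([t0]), np.array([t1]))[0]
    ent1 = _entropy_rows(l0, l1)
    ent2 = _entropy_rows(r0, r1)
    gain = ent - (n1 / n) * ent1 - (n2 / n) * ent2
    k = float(int(t0 > 0) + int(t1 > 0))
    k1 = (l0 > 0).astype(float) + (l1 > 0).astype(float)
    k2 = (r0 > 0).astype(float) + (r1 > 0).astype(float)
    delta = np.log2(3.0**k - 2.0) - (k * ent - k1 * ent1 - k2 * ent2)
    threshold = (np.log2(max(n - 1.0, 1.0)) + delta) / n
    accepted = gain > threshold
    if not np.any(accepted):
        return None
    best = np.flatnonzero(accepted)[np.argmax(gain[accepted])]
    b = boundaries[best]
    return float((xs[b] + xs[b + 1]) / 2.0)


def _recursive_cuts(x, y, w, depth=0, max_depth=32) -> list[float]:
    if depth >= max_depth:
        return []
    cut = _best_cut(x, y, w)
    if cut is None:
        return []
    left = x <= cut
    return (
        _recursive_cuts(x[left], y[left], w[left], depth + 1, max_depth)
        + [cut]
        + _recursive_cuts(x[~left], y[~left], w[~left], depth + 1, max_depth)
    )


@dataclass
class DiscretizationMap:
    """Fitted per-feature cut points. Features without cuts map to one bin.

    The bin convention is right-closed on the left bin: ``x <= cut``
    falls in the lower bin. Missing values keep NaN and are treated as
    their own category downstream.
    """

    cuts: dict[str, list[float]] = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)
    numeric_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "numeric_features": list(self.numeric_features),
            "cuts": {k: [float(c) for c in v] for k, v in self.cuts.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscretizationMap":
        return cls(
            cuts={k: list(v) for k, v in d.get("cuts", {}).items()},
            feature_names=list(d.get("feature_names", [])),
            numeric_features=list(d.get("numeric_features", [])),
        )


def mdl_discretize_column(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> list[float]:
    """Fayyad–Irani MDL cut points for one numeric column.

    Missing values are ignored during the cut search. A constant or
    uninformative column yields no cuts.
    """
    x = np.asarray(x, dtype=float)
    mask = ~np.isnan(x)
    if mask.sum() < 2:
        return []
    cuts = _recursive_cuts(x[mask], np.asarray(y)[mask], np.asarray(w, float)[mask])
    return sorted(cuts)


def fit_discretization(
    dataset: WeightedDataset,
    numeric_features: list[str] | None = None,
) -> DiscretizationMap:
    """Fit MDL cut points for every numeric feature of a dataset."""
    if numeric_features is None:
        numeric_features = list(dataset.feature_names)
    cuts = {}
    for name in numeric_features:
        j = dataset.feature_names.index(name)
        cuts[name] = mdl_discretize_column(dataset.X[:, j], dataset.y, dataset.w)
    return DiscretizationMap(
        cuts=cuts,
        feature_names=list(dataset.feature_names),
        numeric_features=list(numeric_features),
    )


def apply_discretization(dmap: DiscretizationMap, X: np.ndarray,
                         feature_names: list[str] | None = None) -> np.ndarray:
    """Map numeric values to bin indices using fitted cut points.

    Values beyond the fitted range land in the nearest end bin (a
    consequence of ``searchsorted`` on the cut list); NaN stays NaN.
    Non-numeric (categorical-coded) features pass through unchanged.
    """
    names = feature_names if feature_names is not None else dmap.feature_names
    X = np.asarray(X, dtype=float)
    out = X.copy()
    for j, name in enumerate(names):
        if name not in dmap.numeric_features:
            continue
        col = X[:, j]
        mask = ~np.isnan(col)
        cuts = dmap.cuts.get(name)
        if not cuts:
            out[mask, j] = 0.0  # cut-free feature collapses to a single bin
            continue
        # x <= cut -> lower bin, hence side="left" on the sorted cuts
        out[mask, j] = np.searchsorted(np.asarray(cuts), col[mask], side="left")
    return out
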