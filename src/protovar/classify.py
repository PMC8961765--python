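"""Three weighted probabilistic binary classifiers behind one contract.

Every model exposes ``fit(dataset: WeightedDataset)`` and
``predict_proba(X) -> P(pathogenic)`` and respects per-instance weights
exactly as instance replication:

* :class:`LogitBoostClassifier` — additive logistic regression over
  weighted decision stumps (two-class convention ``p = 1/(1+e^{-2F})``);
* :class:`SimpleLogisticClassifier` — the same boosting machinery with
  single-attribute linear-regression base learners and the number of
  iterations chosen by internal 5-fold cross-validation;
* :class:`HoeffdingTreeClassifier` — an incremental decision tree that
  splits a leaf once the information-gain lead of the best attribute
  exceeds the Hoeffding bound.

Missing feature values (NaN) are first-class: stumps and tree nodes give
them their own branch; the logistic variants impute zero after weighted
standardization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import WeightedDataset

ALGORITHMS = ("logitboost", "simple_logistic", "hoeffding_tree")

_P_CLIP = 1e-5
_Z_MAX = 3.0


def _check_binary(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")


def _clip_proba(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _P_CLIP, 1.0 - _P_CLIP)


def _working_response(y: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """LogitBoost working responses and case weights, clamped for stability."""
    p = _clip_proba(p)
    z = np.clip((y - p) / (p * (1.0 - p)), -_Z_MAX, _Z_MAX)
    return z, p * (1.0 - p)


# ---------------------------------------------------------------------------
# decision stump (weighted least-squares regression stump)

@dataclass
class _Stump:
    feature: int
    threshold: float
    left_value: float
    right_value: float
    missing_value: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        col = X[:, self.feature]
        out = np.where(col <= self.threshold, self.left_value, self.right_value)
        return np.where(np.isnan(col), self.missing_value, out)


def _presort_features(X: np.ndarray):
    """Per-feature sort orders and split boundaries, computed once per fit."""
    pre = []
    for j in range(X.shape[1]):
        col = X[:, j]
        mask = ~np.isnan(col)
        idx = np.flatnonzero(mask)
        if len(idx) < 2:
            pre.append(None)
            continue
        order = np.argsort(col[idx], kind="mergesort")
        idx = idx[order]
        xs = col[idx]
        boundaries = np.flatnonzero(np.diff(xs) > 0)
        if len(boundaries) == 0:
            pre.append(None)
            continue
        pre.append((idx, xs, boundaries, np.flatnonzero(~mask)))
    return pre


def _fit_stump(X: np.ndarray, z: np.ndarray, w: np.ndarray,
               pre=None) -> _Stump:
    """Weighted least-squares regression stump over all features.

    For each feature the threshold minimizing weighted squared error is
    found by a sorted sweep; missing values get their own leaf.
    """
    w = np.asarray(w, float)
    if pre is None:
        pre = _presort_features(X)
    best = None
    best_score = -np.inf
    for j, entry in enumerate(pre):
        if entry is None:
            continue
        idx, xs, boundaries, miss_idx = entry
        ws, zs = w[idx], z[idx]
        cw = np.cumsum(ws)
        cwz = np.cumsum(ws * zs)
        W, S = cw[-1], cwz[-1]
        wl, sl = cw[boundaries], cwz[boundaries]
        wr, sr = W - wl, S - sl
        explained = sl**2 / wl + sr**2 / wr  # larger = smaller SSE
        i = int(np.argmax(explained))
        if explained[i] > best_score:
            b = boundaries[i]
            w_miss = w[miss_idx].sum()
            missing_value = (
                float((w[miss_idx] * z[miss_idx]).sum() / w_miss)
                if w_miss > 0 else float(S / W)
            )
            best = _Stump(
                feature=j,
                threshold=float((xs[b] + xs[b + 1]) / 2.0),
                left_value=float(sl[i] / wl[i]),
                right_value=float(sr[i] / wr[i]),
                missing_value=missing_value,
            )
            best_score = float(explained[i])
    if best is None:
        # every feature constant: a single leaf equal to the weighted mean
        mean = float(np.average(z, weights=w))
        best = _Stump(0, np.inf, mean, mean, mean)
    return best


class LogitBoostClassifier:
    """LogitBoost with decision stumps (two-class additive logistic model)."""

    algorithm_id = "logitboost"

    def __init__(self, n_iterations: int = 10, seed: int = 0):
        self.n_iterations = n_iterations
        self.seed = seed
        self.stumps_: list[_Stump] = []
        self.feature_names_: list[str] = []

    def fit(self, dataset: WeightedDataset) -> "LogitBoostClassifier":
        _check_binary(dataset.y)
        X, y, w = dataset.X, dataset.y.astype(float), dataset.w
        self.feature_names_ = list(dataset.feature_names)
        self.stumps_ = []
        pre = _presort_features(X)
        F = np.zeros(len(y))
        p = np.full(len(y), 0.5)
        for _ in range(self.n_iterations):
            z, case_w = _working_response(y, p)
            stump = _fit_stump(X, z, w * case_w, pre)
            self.stumps_.append(stump)
            F += 0.5 * stump.predict(X)
            p = 1.0 / (1.0 + np.exp(-2.0 * F))
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names_):
            raise ValueError(
                f"expected {len(self.feature_names_)} features, got {X.shape[1]}"
            )
        F = np.zeros(len(X))
        for stump in self.stumps_:
            F += 0.5 * stump.predict(X)
        return F

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-2.0 * self.decision_function(X)))


# ---------------------------------------------------------------------------
# simple logistic (boosted single-attribute linear regressions, CV-stopped)

@dataclass
class _SimpleRegression:
    feature: int
    slope: float
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        col = X[:, self.feature]
        col = np.where(np.isnan(col), 0.0, col)  # standardized, so 0 = mean
        return self.intercept + self.slope * col


def _regression_sweep(Xf, X2, z, w) -> _SimpleRegression:
    """One weighted simple-regression sweep over all (imputed) attributes.

    ``Xf`` must be NaN-free and ``X2`` its elementwise square (hoisted
    by the caller because they are loop-invariant during boosting).
    The winner minimizes weighted residual SSE, ties toward the lowest
    attribute index.
    """
    W = w.sum()
    zm = float(w @ z / W)
    zc = z - zm
    xm = (Xf.T @ w) / W
    sxx = X2.T @ w - W * xm**2
    sxz = Xf.T @ (w * zc)  # sum(w * zc) == 0, so no xm correction needed
    ok = sxx > 1e-12
    slope = np.where(ok, sxz / np.where(ok, sxx, 1.0), 0.0)
    sse = float(w @ zc**2) - slope * sxz
    j = int(np.argmin(sse))
    return _SimpleRegression(j, float(slope[j]), float(zm - slope[j] * xm[j]))


def _fit_simple_regression(X, z, w) -> _SimpleRegression:
    """Weighted simple linear regression on the single best attribute."""
    w = np.asarray(w, float)
    Xf = np.where(np.isnan(X), 0.0, X)
    return _regression_sweep(Xf, Xf**2, np.asarray(z, float), w)


class SimpleLogisticClassifier:
    """Additive logistic regression with CV-chosen boosting length.

    Categorical attributes (declared by column name) are one-hot
    expanded internally; all attributes are standardized with weighted
    moments and missing values imputed at zero (the standardized mean).
    """

    algorithm_id = "simple_logistic"

    def __init__(self, max_iterations: int = 30, cv_folds: int = 5,
                 categorical: set[str] | None = None, seed: int = 0):
        self.max_iterations = max_iterations
        self.cv_folds = cv_folds
        self.categorical = set(categorical or ())
        self.seed = seed
        self.regressions_: list[_SimpleRegression] = []
        self.feature_names_: list[str] = []

    # -- internal encoding ------------------------------------------------
    def _fit_encoding(self, X: np.ndarray, names: list[str], w: np.ndarray):
        self._onehot: list[tuple[int, list[float]]] = []
        cols = []
        expanded_names = []
        for j, name in enumerate(names):
            if name in self.categorical:
                values = sorted(set(X[~np.isnan(X[:, j]), j].tolist()))
                self._onehot.append((j, values))
                for v in values:
                    cols.append((X[:, j] == v).astype(float))
                    expanded_names.append(f"{name}={v:g}")
            else:
                self._onehot.append((j, []))
                cols.append(X[:, j])
                expanded_names.append(name)
        Xe = np.column_stack(cols) if cols else np.zeros((len(X), 0))
        W = w.sum()
        mean = np.array([
            (w[~np.isnan(c)] * c[~np.isnan(c)]).sum() / max(w[~np.isnan(c)].sum(), 1e-12)
            for c in Xe.T
        ])
        var = np.array([
            (w[~np.isnan(c)] * (c[~np.isnan(c)] - m) ** 2).sum()
            / max(w[~np.isnan(c)].sum(), 1e-12)
            for c, m in zip(Xe.T, mean)
        ])
        self._mean, self._scale = mean, np.sqrt(np.maximum(var, 1e-12))
        self._expanded_names = expanded_names
        return self._transform_encoded(Xe)

    def _encode(self, X: np.ndarray) -> np.ndarray:
        cols = []
        for j, values in self._onehot:
            if values:
                for v in values:
                    col = (X[:, j] == v).astype(float)
                    col[np.isnan(X[:, j])] = np.nan
                    cols.append(col)
            else:
                cols.append(X[:, j])
        Xe = np.column_stack(cols) if cols else np.zeros((len(X), 0))
        return self._transform_encoded(Xe)

    def _transform_encoded(self, Xe: np.ndarray) -> np.ndarray:
        Xs = (Xe - self._mean) / self._scale
        return np.where(np.isnan(Xe), 0.0, Xs)

    # -- boosting ---------------------------------------------------------
    @staticmethod
    def _boost_path(X, y, w, n_iter):
        Xf = np.where(np.isnan(X), 0.0, X)
        X2 = Xf**2
        F = np.zeros(len(y))
        p = np.full(len(y), 0.5)
        path = []
        for _ in range(n_iter):
            z, case_w = _working_response(y, p)
            reg = _regression_sweep(Xf, X2, z, w * case_w)
            path.append(reg)
            F += 0.5 * (reg.intercept + reg.slope * Xf[:, reg.feature])
            p = 1.0 / (1.0 + np.exp(-2.0 * F))
        return path

    def fit(self, dataset: WeightedDataset) -> "SimpleLogisticClassifier":
        _check_binary(dataset.y)
        self.feature_names_ = list(dataset.feature_names)
        y, w = dataset.y.astype(float), dataset.w
        X = self._fit_encoding(dataset.X, self.feature_names_, w)

        # choose the boosting length by internal cross-validated log-loss
        rng = np.random.default_rng(self.seed)
        n = len(y)
        folds = np.zeros(n, dtype=int)
        for cls in (0, 1):
            idx = np.flatnonzero(dataset.y == cls)
            rng.shuffle(idx)
            folds[idx] = np.arange(len(idx)) % self.cv_folds
        cv_loss = np.zeros(self.max_iterations)
        for f in range(self.cv_folds):
            tr, te = folds != f, folds == f
            if len(np.unique(dataset.y[tr])) < 2 or te.sum() == 0:
                continue
            path = self._boost_path(X[tr], y[tr], w[tr], self.max_iterations)
            F = np.zeros(te.sum())
            for m, reg in enumerate(path):
                F += 0.5 * reg.predict(X[te])
                p = _clip_proba(1.0 / (1.0 + np.exp(-2.0 * F)))
                loss = -(w[te] * (y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))).sum()
                cv_loss[m] += loss
        best_m = int(np.argmin(cv_loss)) + 1
        self.n_iterations_ = best_m
        self.regressions_ = self._boost_path(X, y, w, best_m)
        return self

    def coefficients(self) -> dict[str, float]:
        """Aggregate per-attribute slopes of the additive model."""
        coef: dict[str, float] = {}
        for reg in self.regressions_:
            name = self._expanded_names[reg.feature]
            coef[name] = coef.get(name, 0.0) + 0.5 * reg.slope
        return coef

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names_):
            raise ValueError(
                f"expected {len(self.feature_names_)} features, got {X.shape[1]}"
            )
        Xe = self._encode(X)
        F = np.zeros(len(Xe))
        for reg in self.regressions_:
            F += 0.5 * reg.predict(Xe)
        return F

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-2.0 * self.decision_function(X)))


# ---------------------------------------------------------------------------
# Hoeffding tree (incremental, nominal attributes)

_MISSING = "missing"


def _entropy2(w0: float, w1: float) -> float:
    total = w0 + w1
    if total <= 0:
        return 0.0
    h = 0.0
    for c in (w0, w1):
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


@dataclass
class _HNode:
    counts: list = field(default_factory=lambda: [0.0, 0.0])
    stats: dict = field(default_factory=dict)   # attr -> value -> [w0, w1]
    split_attr: int | None = None
    children: dict = field(default_factory=dict)
    weight_since_check: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.split_attr is None

    def proba(self) -> float:
        # Laplace-smoothed P(class 1)
        return (self.counts[1] + 1.0) / (self.counts[0] + self.counts[1] + 2.0)


class HoeffdingTreeClassifier:
    """Incremental decision tree with the Hoeffding split bound.

    Attributes are treated as nominal (the training pipeline feeds
    discretized bin codes); missing values form their own branch. A
    leaf considers splitting after every ``grace`` units of accumulated
    instance weight: the split happens when the information-gain lead
    of the best attribute over the runner-up exceeds
    ``eps = sqrt(ln(1/delta) / (2 n))`` (range R = log2(2 classes) = 1),
    or when ``eps`` has shrunk below the tie threshold.
    """

    algorithm_id = "hoeffding_tree"

    def __init__(self, delta: float = 1e-7, grace: float = 200.0,
                 tie_threshold: float = 0.05, seed: int = 0):
        self.delta = delta
        self.grace = grace
        self.tie_threshold = tie_threshold
        self.seed = seed
        self.root_: _HNode | None = None
        self.feature_names_: list[str] = []

    @staticmethod
    def hoeffding_bound(delta: float, n: float) -> float:
        return math.sqrt(math.log(1.0 / delta) / (2.0 * n))

    @staticmethod
    def _value_key(v: float):
        return _MISSING if np.isnan(v) else float(v)

    def _route(self, node: _HNode, x: np.ndarray) -> _HNode:
        while not node.is_leaf:
            key = self._value_key(x[node.split_attr])
            child = node.children.get(key)
            if child is None:
                child = _HNode()
                node.children[key] = child
            node = child
        return node

    def _gains(self, node: _HNode, n_features: int):
        base = _entropy2(*node.counts)
        total = node.counts[0] + node.counts[1]
        gains = []
        for j in range(n_features):
            by_value = node.stats.get(j, {})
            if len(by_value) < 2:
                gains.append((0.0, j))
                continue
            rem = 0.0
            for w0, w1 in by_value.values():
                rem += (w0 + w1) / total * _entropy2(w0, w1)
            gains.append((base - rem, j))
        gains.sort(key=lambda t: (-t[0], t[1]))
        return gains

    def _try_split(self, node: _HNode, n_features: int) -> None:
        total = node.counts[0] + node.counts[1]
        if total <= 0 or min(node.counts) == 0:
            return  # pure leaf, nothing to gain
        gains = self._gains(node, n_features)
        g1, j1 = gains[0]
        g2 = gains[1][0] if len(gains) > 1 else 0.0
        eps = self.hoeffding_bound(self.delta, total)
        if g1 > 0 and (g1 - g2 > eps or eps < self.tie_threshold):
            node.split_attr = j1
            node.children = {}
            for value, (w0, w1) in node.stats.get(j1, {}).items():
                child = _HNode()
                child.counts = [w0, w1]
                node.children[value] = child
            node.stats = {}

    def fit(self, dataset: WeightedDataset) -> "HoeffdingTreeClassifier":
        _check_binary(dataset.y)
        self.feature_names_ = list(dataset.feature_names)
        n_features = dataset.X.shape[1]
        self.root_ = _HNode()
        for x, label, weight in zip(dataset.X, dataset.y, dataset.w):
            leaf = self._route(self.root_, x)
            leaf.counts[label] += weight
            for j in range(n_features):
                key = self._value_key(x[j])
                cell = leaf.stats.setdefault(j, {}).setdefault(key, [0.0, 0.0])
                cell[label] += weight
            leaf.weight_since_check += weight
            if leaf.weight_since_check >= self.grace:
                leaf.weight_since_check = 0.0
                self._try_split(leaf, n_features)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names_):
            raise ValueError(
                f"expected {len(self.feature_names_)} features, got {X.shape[1]}"
            )
        out = np.empty(len(X))
        for i, x in enumerate(X):
            node = self.root_
            while node is not None and not node.is_leaf:
                nxt = node.children.get(self._value_key(x[node.split_attr]))
                if nxt is None:
                    break  # unseen branch: predict from this node's counts
                node = nxt
            out[i] = node.proba()
        return out


# ---------------------------------------------------------------------------

def make_classifier(algorithm_id: str, seed: int = 0,
                    categorical: set[str] | None = None):
    """Instantiate one of the three algorithms by id."""
    if algorithm_id == "logitboost":
        return LogitBoostClassifier(seed=seed)
    if algorithm_id == "simple_logistic":
        return SimpleLogisticClassifier(seed=seed, categorical=categorical)
    if algorithm_id == "hoeffding_tree":
        return HoeffdingTreeClassifier(seed=seed)
    raise ValueError(f"unknown algorithm {algorithm_id!r}; choose from {ALGORITHMS}")
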