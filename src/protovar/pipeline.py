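"""Per-gene training pipeline: balance, discretize, classify.

A :class:`GenePipeline` bundles the two supervised filters with one of
the three classifiers behind a plain fit/predict contract, so the
cross-validation engine can treat preprocessing as part of the model
and fit everything inside each training fold (no information from a
test fold ever reaches the filters).
"""

from __future__ import annotations

import hashlib
import json

import numpy as np

from .annotate import BOOLEAN_FEATURES, CATEGORICAL_FEATURES, NUMERIC_FEATURES
from .classify import make_classifier
from .datamodel import WeightedDataset
from .preprocess import (
    DiscretizationMap,
    apply_discretization,
    class_balance,
    fit_discretization,
)


class GenePipeline:
    """Class balancing + MDL discretization + a chosen classifier.

    ``frozen_discretization`` bypasses per-fit discretization with a
    pre-fitted map; this exists only for leakage diagnostics and must
    never be used in honest evaluation.
    """

    def __init__(
        self,
        algorithm_id: str = "logitboost",
        numeric_features: list[str] | None = None,
        categorical_features: set[str] | None = None,
        balance: bool = True,
        discretize: bool = True,
        seed: int = 0,
        frozen_discretization: DiscretizationMap | None = None,
    ):
        self.algorithm_id = algorithm_id
        self.numeric_features = numeric_features
        self.categorical_features = categorical_features
        self.balance = balance
        self.discretize = discretize
        self.seed = seed
        self.frozen_discretization = frozen_discretization

    def _numeric_in(self, names: list[str]) -> list[str]:
        if self.numeric_features is not None:
            return [n for n in names if n in self.numeric_features]
        # catalogue booleans/categoricals are already nominal; any name
        # outside the catalogue is assumed to be a numeric measurement
        nominal = set(CATEGORICAL_FEATURES) | BOOLEAN_FEATURES
        return [n for n in names if n in NUMERIC_FEATURES or n not in nominal]

    def _categorical_in(self, names: list[str]) -> set[str]:
        pool = self.categorical_features if self.categorical_features is not None \
            else set(CATEGORICAL_FEATURES)
        return {n for n in names if n in pool}

    def fit(self, dataset: WeightedDataset) -> "GenePipeline":
        if self.balance:
            dataset = class_balance(dataset)
        self.feature_names_ = list(dataset.feature_names)
        if self.discretize:
            if self.frozen_discretization is not None:
                self.dmap_ = self.frozen_discretization
            else:
                self.dmap_ = fit_discretization(
                    dataset, self._numeric_in(dataset.feature_names)
                )
            X = apply_discretization(self.dmap_, dataset.X, dataset.feature_names)
            dataset = WeightedDataset(X, dataset.y, dataset.w, dataset.feature_names)
            # discretized numerics are nominal bins for the logistic expansion
            categorical = self._categorical_in(dataset.feature_names) | set(
                self.dmap_.numeric_features
            )
        else:
            self.dmap_ = None
            categorical = self._categorical_in(dataset.feature_names)
        self.classifier_ = make_classifier(
            self.algorithm_id, seed=self.seed, categorical=categorical
        )
        self.classifier_.fit(dataset)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.dmap_ is not None:
            X = apply_discretization(self.dmap_, X, self.feature_names_)
        return self.classifier_.predict_proba(X)


def manifest_hash(payload: dict) -> str:
    """Stable SHA-256 over a JSON-serializable run manifest."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
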