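"""Random forest with explicit out-of-bag bookkeeping.

The ensemble is a hand-rolled bagging loop over sklearn decision trees so
that every tree's bootstrap (in-bag) index multiset is recorded; the
out-of-bag (OOB) set of a tree is the complement.  That record is what the
permutation importance needs::

    J(x_j) = (1/T) * sum_k (1/|B_k|) *
             [ sum_{i in B_k} I(h_k^{pi_j}(i) != y_i) - I(h_k(i) != y_i) ]

where B_k is tree k's OOB set, h_k its prediction, and h_k^{pi_j} its
prediction after permuting feature x_j within B_k.  A feature whose
permutation helps rather than hurts gets a negative importance; values are
deliberately not clipped.

Prediction is by majority vote over trees, ties broken toward the
lexicographically smallest class label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ForestConfig",
    "Forest",
    "GridSearchResult",
    "fit_forest",
    "oob_importance",
    "grid_search",
]


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters; (max_depth, n_trees) = (20, 200) by default.

    Trees use Gini impurity with sqrt(|F|) candidate features per split and
    no pruning beyond the depth bound.
    """

    n_trees: int = 200
    max_depth: int = 20
    seed: int = 0
    oob: bool = True
    max_features: str | int | float = "sqrt"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "max_depth": self.max_depth,
            "seed": self.seed,
            "oob": self.oob,
            "max_features": self.max_features,
        }


def _coerce_X(features, expected_names: tuple[str, ...] | None = None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, pd.DataFrame):
        names = tuple(str(c) for c in features.columns)
        X = features.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(features, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        names = tuple(f"f{i}" for i in range(X.shape[1]))
        if expected_names is not None and len(expected_names) == X.shape[1]:
            names = expected_names  # plain arrays are accepted positionally
    if expected_names is not None and names != expected_names:
        missing = sorted(set(expected_names) - set(names))
        extra = sorted(set(names) - set(expected_names))
        raise ValueError(
            f"feature columns do not match training columns; "
            f"missing={missing}, extra={extra}, "
            f"or order differs"
        )
    return X, names


@dataclass
class Forest:
    """A trained bagged tree ensemble with per-tree in-bag records."""

    trees: list[DecisionTreeClassifier]
    inbag: list[np.ndarray]  # per tree, the bootstrap index multiset (length N)
    classes: tuple[str, ...]  # lexicographically sorted
    feature_names: tuple[str, ...]
    config: ForestConfig
    n_samples: int

    def oob_indices(self, k: int) -> np.ndarray:
        """Indices of training samples not drawn into tree k's bootstrap."""
        mask = np.ones(self.n_samples, dtype=bool)
        mask[self.inbag[k]] = False
        return np.flatnonzero(mask)

    def predict_proba(self, features) -> np.ndarray:
        """Vote fractions per class; rows sum to 1."""
        X, _ = _coerce_X(features, self.feature_names)
        votes = np.zeros((X.shape[0], len(self.classes)))
        class_arr = np.asarray(self.classes, dtype=object)
        rows = np.arange(X.shape[0])
        for tree in self.trees:
            codes = np.searchsorted(class_arr, tree.predict(X))
            np.add.at(votes, (rows, codes), 1.0)
        return votes / len(self.trees)

    def predict(self, features) -> np.ndarray:
        """Majority-vote labels; ties go to the lexicographically smallest class."""
        proba = self.predict_proba(features)
        # classes are sorted, so argmax's first-max rule is the lexicographic tie-break
        return np.asarray(self.classes, dtype=object)[proba.argmax(axis=1)]

    def score(self, features, labels) -> float:
        return float(np.mean(self.predict(features) == np.asarray(labels, dtype=object)))


def fit_forest(features, labels: Sequence, config: ForestConfig = ForestConfig()) -> Forest:
    """Fit ``n_trees`` depth-bounded trees, each on a bootstrap sample of size N."""
    X, names = _coerce_X(features)
    y = np.asarray([str(v) for v in labels], dtype=object)
    if len(y) != X.shape[0]:
        raise ValueError("features and labels must have equal length")
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes, got {classes}")
    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    trees: list[DecisionTreeClassifier] = []
    inbag: list[np.ndarray] = []
    tree_seeds = rng.integers(0, 2**31 - 1, size=config.n_trees)
    for k in range(config.n_trees):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_depth=config.max_depth,
            max_features=config.max_features,
            random_state=int(tree_seeds[k]),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        inbag.append(idx)
    return Forest(trees=trees, inbag=inbag, classes=classes, feature_names=names,
                  config=config, n_samples=n)


def oob_importance(
    forest: Forest,
    features,
    labels: Sequence,
    seed: int = 0,
    n_repeats: int = 1,
) -> pd.Series:
    """Out-of-bag permutation importance per feature.

    ``features``/``labels`` must be the training set the forest was fitted
    on (the in-bag records refer to its row order).  Each tree contributes
    the increase in its OOB misclassification count after permuting one
    feature within its OOB set, normalized by the OOB size; the average
    over trees is returned as a Series indexed by feature name.
    """
    if not forest.config.oob:
        raise ValueError("forest was not fitted with oob bookkeeping enabled")
    X, _ = _coerce_X(features, forest.feature_names)
    y = np.asarray([str(v) for v in labels], dtype=object)
    if X.shape[0] != forest.n_samples:
        raise ValueError("features must be the training set the forest was fitted on")
    rng = np.random.default_rng(seed)
    n_feat = X.shape[1]
    totals = np.zeros(n_feat)
    used = 0
    for k, tree in enumerate(forest.trees):
        oob = forest.oob_indices(k)
        if len(oob) == 0:
            warnings.warn(f"tree {k} has an empty OOB set; skipped", stacklevel=2)
            continue
        used += 1
        X_oob = X[oob]
        y_oob = y[oob]
        base_err = int(np.sum(tree.predict(X_oob) != y_oob))
        for j in range(n_feat):
            delta = 0.0
            for _ in range(n_repeats):
                perm = rng.permutation(len(oob))
                X_perm = X_oob.copy()
                X_perm[:, j] = X_oob[perm, j]
                delta += int(np.sum(tree.predict(X_perm) != y_oob)) - base_err
            totals[j] += delta / (n_repeats * len(oob))
    if used == 0:
        raise ValueError("every tree had an empty OOB set; cannot compute importance")
    return pd.Series(totals / used, index=list(forest.feature_names), name="importance")


@dataclass
class GridSearchResult:
    """Exhaustive (depth, n_trees) search scored by stratified k-fold CV accuracy."""

    grid: list[tuple[int, int]]
    cv_scores: list[float]
    best: tuple[int, int]
    n_folds: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "max_depth": [d for d, _ in self.grid],
                "n_trees": [n for _, n in self.grid],
                "mean_cv_accuracy": self.cv_scores,
            }
        )


def grid_search(
    features,
    labels: Sequence,
    d_range: Sequence[int] = range(10, 31),
    n_range: Sequence[int] = range(190, 231),
    n_folds: int = 5,
    seed: int = 0,
    base_config: ForestConfig = ForestConfig(),
) -> GridSearchResult:
    """Evaluate every (depth, n_trees) candidate by stratified CV mean accuracy.

    Ties are broken toward the smallest depth, then the smallest tree
    count, so the result is deterministic and invariant to grid ordering.
    """
    cands = sorted(set(product((int(d) for d in d_range), (int(n) for n in n_range))))
    if not cands:
        raise ValueError("empty parameter grid")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    X, _ = _coerce_X(features)
    y = np.asarray([str(v) for v in labels], dtype=object)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < n_folds={n_folds}; "
            f"use fewer folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    scores: list[float] = []
    for d, n in cands:
        cfg = ForestConfig(n_trees=n, max_depth=d, seed=base_config.seed,
                           oob=False, max_features=base_config.max_features)
        accs = []
        for train_idx, test_idx in folds:
            f = fit_forest(X[train_idx], y[train_idx], cfg)
            accs.append(f.score(X[test_idx], y[test_idx]))
        scores.append(float(np.mean(accs)))
    best_i = max(range(len(cands)), key=lambda i: (scores[i], -cands[i][0], -cands[i][1]))
    return GridSearchResult(grid=cands, cv_scores=scores, best=cands[best_i], n_folds=n_folds)
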