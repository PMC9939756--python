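"""The SARF composite model: self-attention feature refinement + random forest.

Usage follows the model/results idiom::

    model = SARF.from_dataframe(feature_table)       # 'label' column holds y
    res = model.fit()
    res.predict(new_features)
    res.global_attention            # R_G, a distribution over features
    res.importance()                # OOB permutation importance J
    print(res.summary())

``fit`` trains the attention network on the raw features, derives the
global attention vector R_G, residually reweights the features
(``fused = F + F * |F| * R_G``), and fits the bagged tree ensemble on the
fused features.  ``tune`` grid-searches (tree depth, tree count) by
stratified cross-validation on the fused features before the final fit.
Every source of randomness flows from the two configs' seeds, so a fitted
model is bit-reproducible.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .attention import (
    AttentionModel,
    AttentionWeights,
    SANConfig,
    fuse_features,
    global_attention,
    train_san,
)
from .forest import Forest, ForestConfig, GridSearchResult, fit_forest, grid_search, oob_importance

__all__ = ["SARF", "SARFResults"]


class SARF:
    """Self-Attention Random Forest model specification.

    Parameters
    ----------
    features : DataFrame or 2-D array
        Texture (or any tabular) features; DataFrame columns become
        feature names.
    labels : sequence
        Class labels, one per row.
    san_config, forest_config : optional
        Hyperparameters for the attention network and the forest;
        defaults are 20 epochs / batch 16 / Adam 1e-3 / dropout 0.2 and
        (depth, trees) = (20, 200).
    """

    def __init__(
        self,
        features,
        labels: Sequence,
        san_config: SANConfig | None = None,
        forest_config: ForestConfig | None = None,
    ) -> None:
        if isinstance(features, pd.DataFrame):
            self.features = features.copy()
        else:
            X = np.asarray(features, dtype=np.float64)
            self.features = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        self.labels = np.asarray([str(v) for v in labels], dtype=object)
        if len(self.labels) != len(self.features):
            raise ValueError("features and labels must have equal length")
        self.san_config = san_config or SANConfig()
        self.forest_config = forest_config or ForestConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        san_config: SANConfig | None = None,
        forest_config: ForestConfig | None = None,
    ) -> "SARF":
        """Build from a feature table whose ``label_col`` holds the classes."""
        if label_col not in df.columns:
            raise ValueError(f"column {label_col!r} not found in DataFrame")
        return cls(
            df.drop(columns=[label_col]),
            df[label_col].to_numpy(),
            san_config=san_config,
            forest_config=forest_config,
        )

    def fit(self) -> "SARFResults":
        """Train attention, fuse features, fit the forest."""
        attention_model = train_san(self.features, self.labels, self.san_config)
        weights = global_attention(attention_model)
        fused = fuse_features(self.features, weights,
                              rescale=self.san_config.rescale_attention)
        forest = fit_forest(fused, self.labels, self.forest_config)
        return SARFResults(model=self, attention_model=attention_model,
                           attention=weights, forest=forest)

    def tune(
        self,
        d_range: Sequence[int] = range(10, 31),
        n_range: Sequence[int] = range(190, 231),
        n_folds: int = 5,
        seed: int = 0,
    ) -> tuple[GridSearchResult, "SARFResults"]:
        """Grid-search (depth, n_trees) on fused features, then refit at the best.

        The attention network is trained once; the grid is scored by
        stratified ``n_folds``-fold CV mean accuracy on the fused features.
        """
        attention_model = train_san(self.features, self.labels, self.san_config)
        weights = global_attention(attention_model)
        fused = fuse_features(self.features, weights,
                              rescale=self.san_config.rescale_attention)
        result = grid_search(fused, self.labels, d_range=d_range, n_range=n_range,
                             n_folds=n_folds, seed=seed, base_config=self.forest_config)
        best_d, best_n = result.best
        cfg = ForestConfig(n_trees=best_n, max_depth=best_d,
                           seed=self.forest_config.seed, oob=self.forest_config.oob,
                           max_features=self.forest_config.max_features)
        forest = fit_forest(fused, self.labels, cfg)
        res = SARFResults(model=self, attention_model=attention_model,
                          attention=weights, forest=forest, grid_result=result)
        return result, res


@dataclass
class SARFResults:
    """Fitted SARF: attention network, global attention, and forest."""

    model: SARF
    attention_model: AttentionModel
    attention: AttentionWeights
    forest: Forest
    grid_result: GridSearchResult | None = None

    @property
    def global_attention(self) -> pd.Series:
        """R_G as a Series over feature names (non-negative, sums to 1)."""
        return pd.Series(self.attention.r_g, index=list(self.attention.feature_names),
                         name="r_g")

    @property
    def classes(self) -> tuple[str, ...]:
        return self.forest.classes

    def _fuse(self, features) -> pd.DataFrame | np.ndarray:
        return fuse_features(features, self.attention,
                             rescale=self.model.san_config.rescale_attention)

    def predict(self, features) -> np.ndarray:
        """Majority-vote class labels for raw (unfused) features."""
        return self.forest.predict(self._fuse(features))

    def predict_proba(self, features) -> np.ndarray:
        """Vote fractions per class (columns in ``self.classes`` order)."""
        return self.forest.predict_proba(self._fuse(features))

    def score(self, features, labels) -> float:
        """Plain accuracy in [0, 1] on raw features."""
        return float(np.mean(self.predict(features) == np.asarray(labels, dtype=object)))

    def importance(self, features=None, labels=None, seed: int = 0,
                   n_repeats: int = 1) -> pd.Series:
        """OOB permutation importance on the (fused) training features."""
        if features is None:
            features = self.model.features
            labels = self.model.labels
        elif labels is None:
            raise ValueError("labels must accompany features")
        return oob_importance(self.forest, self._fuse(features), labels,
                              seed=seed, n_repeats=n_repeats)

    def importance_report(self, seed: int = 0) -> pd.DataFrame:
        """Per-feature table of permutation importance J and attention r_g."""
        imp = self.importance(seed=seed)
        return pd.DataFrame({
            "feature_name": imp.index,
            "importance": imp.to_numpy(),
            "r_g": self.attention.r_g,
        })

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary with the top attention-weighted features."""
        cfg_f = self.forest.config
        cfg_s = self.model.san_config
        train_acc = self.score(self.model.features, self.model.labels)
        r = self.global_attention.sort_values(ascending=False)
        lines = [
            "Self-Attention Random Forest Results",
            "=" * 54,
            f"N observations:     {len(self.model.labels)}",
            f"N features:         {self.model.features.shape[1]}",
            f"Classes:            {', '.join(self.classes)}",
            f"Attention heads:    {cfg_s.n_heads}   epochs: {cfg_s.epochs}   "
            f"batch: {cfg_s.batch_size}",
            f"Forest:             {cfg_f.n_trees} trees, max depth {cfg_f.max_depth}",
            f"Final SAN loss:     {self.attention_model.loss_trace[-1]:.4f}",
            f"Training accuracy:  {100 * train_acc:.2f}%",
        ]
        if self.grid_result is not None:
            d, n = self.grid_result.best
            lines.append(f"Grid-search best:   (d, n) = ({d}, {n})")
        lines += ["-" * 54, f"Top {min(top, len(r))} features by global attention R_G:"]
        for name, val in r.head(top).items():
            lines.append(f"  {name:<32s} {val:.4f}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Persist the full fitted model (attention + forest + configs) to one file."""
        with open(Path(path), "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "SARFResults":
        with open(Path(path), "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a SARFResults artifact")
        return obj
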