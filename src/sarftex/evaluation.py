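"""Classification metrics: confusion matrices, per-class rates, ROC/AUC.

Conventions
-----------
* Confusion matrix rows are ground truth, columns are predictions.
* Per-class metrics come from the one-vs-rest reduction of the n x n
  matrix: for class c, TP = N_cc, FN = row c minus TP, FP = column c minus
  TP, TN = everything else.  Then

  - sensitivity  Sen = TP / (TP + FN)
  - specificity  Spe = TN / (TN + FP)
  - positive prediction rate  PPR = TP / (TP + FP)   (precision)
  - negative prediction rate  NPR = TN / (TN + FN)

  reported as percentages at full precision (round only for display).
  A zero denominator yields NaN together with an ``undefined`` flag —
  never silently 0 or 100.
* Multiclass ROC uses micro-averaging: one-hot binarize the truth, pool
  all (label, score) pairs across classes, compute a single curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import sklearn.metrics as _skm

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricReport",
    "ROCCurve",
    "confusion_matrix",
    "overall_accuracy",
    "per_class_metrics",
    "metric_report",
    "roc_curve",
    "micro_average_roc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts N_ij: row i = ground truth, column j = prediction."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        n = len(self.class_names)
        if c.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("confusion matrix is empty (total count 0)")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names),
                            columns=list(self.class_names))


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest counts and rates (percent) for a single class."""

    tp: int
    fn: int
    fp: int
    tn: int
    sen: float
    spe: float
    ppr: float
    npr: float
    undefined: tuple[str, ...] = ()  # names of rates with zero denominators


@dataclass(frozen=True)
class MetricReport:
    accuracy: float  # percent
    per_class: dict[str, ClassMetrics]
    cm: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "accuracy_percent": self.accuracy,
            "class_names": list(self.cm.class_names),
            "confusion_matrix": self.cm.counts.tolist(),
            "per_class": {
                name: {
                    "TP": m.tp, "FN": m.fn, "FP": m.fp, "TN": m.tn,
                    "sen_percent": None if "sen" in m.undefined else m.sen,
                    "spe_percent": None if "spe" in m.undefined else m.spe,
                    "ppr_percent": None if "ppr" in m.undefined else m.ppr,
                    "npr_percent": None if "npr" in m.undefined else m.npr,
                    "undefined": list(m.undefined),
                }
                for name, m in self.per_class.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def confusion_matrix(
    truth: Sequence, pred: Sequence, class_names: Sequence[str] | None = None
) -> ConfusionMatrix:
    """Tally truth x prediction counts over ``class_names`` (sorted union by default)."""
    t = [str(v) for v in truth]
    p = [str(v) for v in pred]
    if len(t) != len(p):
        raise ValueError(f"truth and pred lengths differ: {len(t)} vs {len(p)}")
    if len(t) == 0:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    if class_names is None:
        names = tuple(sorted(set(t) | set(p)))
    else:
        names = tuple(str(c) for c in class_names)
        unknown = (set(t) | set(p)) - set(names)
        if unknown:
            raise ValueError(f"labels not in class_names: {sorted(unknown)}")
    counts = _skm.confusion_matrix(t, p, labels=list(names))
    return ConfusionMatrix(counts=counts, class_names=names)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 x trace / total."""
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def per_class_metrics(cm: ConfusionMatrix, class_name: str) -> ClassMetrics:
    """Sen/Spe/PPR/NPR (percent) for one class, one-vs-rest."""
    if class_name not in cm.class_names:
        raise ValueError(f"unknown class {class_name!r}; have {cm.class_names}")
    c = cm.class_names.index(class_name)
    counts = cm.counts
    tp = int(counts[c, c])
    fn = int(counts[c].sum() - tp)
    fp = int(counts[:, c].sum() - tp)
    tn = int(counts.sum() - tp - fn - fp)

    undefined: list[str] = []

    def rate(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return 100.0 * num / den

    sen = rate(tp, tp + fn, "sen")
    spe = rate(tn, tn + fp, "spe")
    ppr = rate(tp, tp + fp, "ppr")
    npr = rate(tn, tn + fn, "npr")
    return ClassMetrics(tp=tp, fn=fn, fp=fp, tn=tn, sen=sen, spe=spe,
                        ppr=ppr, npr=npr, undefined=tuple(undefined))


def metric_report(cm: ConfusionMatrix) -> MetricReport:
    """Overall accuracy plus per-class metrics for every class."""
    return MetricReport(
        accuracy=overall_accuracy(cm),
        per_class={name: per_class_metrics(cm, name) for name in cm.class_names},
        cm=cm,
    )


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr})

    def plot(self, path: str | Path, label: str = "ROC") -> None:
        """Write the curve as a PNG with the chance diagonal for reference."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot(self.fpr, self.tpr, label=f"{label} (AUC = {self.auc:.4f})")
        ax.plot([0, 1], [0, 1], "k--", linewidth=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        fig.savefig(Path(path), dpi=150, bbox_inches="tight")
        plt.close(fig)


def roc_curve(truth: Sequence[int], scores: Sequence[float]) -> ROCCurve:
    """Binary ROC by threshold sweep (equal scores grouped) with trapezoidal AUC."""
    y = np.asarray(truth).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("truth must be binary 0/1 labels")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_skm.auc(fpr, tpr)))


def micro_average_roc(
    truth: Sequence, proba: np.ndarray, class_names: Sequence[str]
) -> ROCCurve:
    """Micro-averaged multiclass ROC: pool one-hot labels and scores across classes."""
    proba = np.asarray(proba, dtype=np.float64)
    names = [str(c) for c in class_names]
    t = [str(v) for v in truth]
    if proba.ndim != 2 or proba.shape[1] != len(names):
        raise ValueError(
            f"proba must be (n_samples, {len(names)}), got {proba.shape}"
        )
    if len(t) != proba.shape[0]:
        raise ValueError("truth and proba row counts differ")
    unknown = set(t) - set(names)
    if unknown:
        raise ValueError(f"labels not in class_names: {sorted(unknown)}")
    onehot = np.asarray([[1 if lbl == c else 0 for c in names] for lbl in t])
    return roc_curve(onehot.ravel(), proba.ravel())
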