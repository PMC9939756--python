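"""Self-attention network (SAN) for per-feature importance weighting.

The SAN is a shallow feed-forward classifier whose first layer multiplies
the input elementwise by a softmax attention distribution over the |F|
features::

    Omega(X) = (1/k) sum_heads X * softmax(W_att X + b_att)

followed by a SELU dense layer, dropout, a sigmoid dense layer, and a
softmax classification head, trained with categorical cross-entropy and
Adam.  After training the softmaxed diagonal of each head's attention
matrix, averaged over heads, is the *global attention* vector R_G — a
probability distribution over features used both as an importance report
and to residually reweight the features fed to the downstream forest:

    fused = F + F * (|F| * R_G)

The |F| rescaling makes uniform attention classifier-neutral (fused = 2F);
it can be disabled via ``SANConfig.rescale_attention``.

Everything is plain numpy with hand-written gradients; training is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SANConfig",
    "AttentionModel",
    "AttentionWeights",
    "softmax",
    "selu",
    "omega_forward",
    "forward",
    "train_san",
    "global_attention",
    "fuse_features",
]

# standard self-normalizing constants (Klambauer et al.)
SELU_LAMBDA = 1.0507
SELU_ALPHA = 1.67326


@dataclass(frozen=True)
class SANConfig:
    """Hyperparameters of the self-attention network.

    Defaults follow common practice for this architecture: 20 epochs,
    batch size 16, Adam learning rate 1e-3, 20% dropout.
    """

    n_heads: int = 1
    hidden_size: int | None = None  # None -> |F|
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    dropout_rate: float = 0.2
    selu_lambda: float = SELU_LAMBDA
    selu_alpha: float = SELU_ALPHA
    rescale_attention: bool = True
    input_scaling: str = "minmax"  # "minmax" | "zscore" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_scaling not in ("minmax", "zscore", "none"):
            raise ValueError(f"unknown input_scaling {self.input_scaling!r}")
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0 or self.selu_lambda <= 0 or self.selu_alpha <= 0:
            raise ValueError("learning_rate, selu_lambda and selu_alpha must be positive")

    def to_dict(self) -> dict:
        return {
            "n_heads": self.n_heads,
            "hidden_size": self.hidden_size,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "dropout_rate": self.dropout_rate,
            "selu_lambda": self.selu_lambda,
            "selu_alpha": self.selu_alpha,
            "rescale_attention": self.rescale_attention,
            "input_scaling": self.input_scaling,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SANConfig":
        return cls(**d)


@dataclass
class AttentionModel:
    """Trained (or freshly initialized) SAN parameters."""

    w_att: list[np.ndarray]  # k matrices, each |F| x |F|
    b_att: list[np.ndarray]  # k vectors, each |F|
    w1: np.ndarray  # hidden x |F|
    b1: np.ndarray
    w2: np.ndarray  # hidden2 x hidden
    b2: np.ndarray
    w_out: np.ndarray  # n_classes x hidden2
    b_out: np.ndarray
    config: SANConfig
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    # input standardization learned on the training set
    scale_mean: np.ndarray | None = None
    scale_std: np.ndarray | None = None
    loss_trace: list[float] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.w1.shape[1]

    def _params(self) -> list[np.ndarray]:
        return [*self.w_att, *self.b_att, self.w1, self.b1, self.w2, self.b2,
                self.w_out, self.b_out]

    def save(self, path: str | Path) -> None:
        """Serialize all weights + config to a single JSON artifact."""
        d = {
            "config": self.config.to_dict(),
            "feature_names": list(self.feature_names),
            "classes": list(self.classes),
            "w_att": [w.tolist() for w in self.w_att],
            "b_att": [b.tolist() for b in self.b_att],
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2.tolist(),
            "w_out": self.w_out.tolist(), "b_out": self.b_out.tolist(),
            "scale_mean": None if self.scale_mean is None else self.scale_mean.tolist(),
            "scale_std": None if self.scale_std is None else self.scale_std.tolist(),
            "loss_trace": self.loss_trace,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def load(cls, path: str | Path) -> "AttentionModel":
        d = json.loads(Path(path).read_text())
        arr = lambda x: np.asarray(x, dtype=np.float64)
        return cls(
            w_att=[arr(w) for w in d["w_att"]],
            b_att=[arr(b) for b in d["b_att"]],
            w1=arr(d["w1"]), b1=arr(d["b1"]),
            w2=arr(d["w2"]), b2=arr(d["b2"]),
            w_out=arr(d["w_out"]), b_out=arr(d["b_out"]),
            config=SANConfig.from_dict(d["config"]),
            feature_names=tuple(d["feature_names"]),
            classes=tuple(d["classes"]),
            scale_mean=None if d["scale_mean"] is None else arr(d["scale_mean"]),
            scale_std=None if d["scale_std"] is None else arr(d["scale_std"]),
            loss_trace=list(d["loss_trace"]),
        )


@dataclass(frozen=True)
class AttentionWeights:
    """Global attention R_G plus the per-head distributions it averages."""

    r_g: np.ndarray
    per_head: tuple[np.ndarray, ...]
    feature_names: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or tuple(f"f{i}" for i in range(len(self.r_g)))
        return pd.DataFrame({"feature_name": list(names), "r_g": self.r_g})


def softmax(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (shift-invariant by construction)."""
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    shifted = v - v.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def selu(x, lam: float = SELU_LAMBDA, alpha: float = SELU_ALPHA):
    """Scaled exponential linear unit: lam*x for x>0, lam*alpha*(e^x - 1) otherwise."""
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x > 0, lam * x, lam * alpha * np.expm1(np.minimum(x, 0.0)))
    return out if out.ndim else float(out)


def _selu_grad(x: np.ndarray, lam: float, alpha: float) -> np.ndarray:
    return np.where(x > 0, lam, lam * alpha * np.exp(np.minimum(x, 0.0)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _as_2d(X) -> tuple[np.ndarray, bool]:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        return X[None, :], True
    return X, False


def omega_forward(X, model: AttentionModel) -> np.ndarray:
    """Attention layer: per head, X * softmax(W_att X + b_att), averaged over heads."""
    X2, was_1d = _as_2d(X)
    if X2.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X2.shape[1]}"
        )
    acc = np.zeros_like(X2)
    for wk, bk in zip(model.w_att, model.b_att):
        attn = softmax(X2 @ wk.T + bk, axis=1)
        acc += X2 * attn
    out = acc / len(model.w_att)
    return out[0] if was_1d else out


def forward(X, model: AttentionModel, return_hidden: bool = False):
    """Inference pass: attention -> SELU dense -> sigmoid dense -> softmax head.

    Dropout is inactive (inference mode), so the pass is deterministic.
    Inputs are standardized with the statistics stored at training time.
    """
    X2, was_1d = _as_2d(X)
    if model.scale_mean is not None:
        X2 = (X2 - model.scale_mean) / model.scale_std
    cfg = model.config
    omega = omega_forward(X2, model)
    h1 = omega @ model.w1.T + model.b1
    s = selu(h1, cfg.selu_lambda, cfg.selu_alpha)
    h2 = s @ model.w2.T + model.b2
    g = _sigmoid(h2)
    logits = g @ model.w_out.T + model.b_out
    probs = softmax(logits, axis=1)
    if return_hidden:
        return probs, omega
    return probs[0] if was_1d else probs


def _init_model(
    n_features: int,
    n_classes: int,
    config: SANConfig,
    feature_names: Sequence[str],
    classes: Sequence[str],
    rng: np.random.Generator,
) -> AttentionModel:
    hidden = config.hidden_size or n_features
    # attention starts at zero -> exactly uniform initial attention
    w_att = [np.zeros((n_features, n_features)) for _ in range(config.n_heads)]
    b_att = [np.zeros(n_features) for _ in range(config.n_heads)]

    def glorot(n_out: int, n_in: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-limit, limit, size=(n_out, n_in))

    return AttentionModel(
        w_att=w_att, b_att=b_att,
        w1=glorot(hidden, n_features), b1=np.zeros(hidden),
        w2=glorot(hidden, hidden), b2=np.zeros(hidden),
        w_out=glorot(n_classes, hidden), b_out=np.zeros(n_classes),
        config=config,
        feature_names=tuple(feature_names),
        classes=tuple(classes),
    )


def train_san(
    features,
    labels: Sequence,
    config: SANConfig = SANConfig(),
) -> AttentionModel:
    """Train the SAN with Adam on categorical cross-entropy.

    ``features`` may be a DataFrame (columns become feature names) or a 2-D
    array.  Inputs are z-scored internally (statistics stored on the model)
    so attention logits stay well-conditioned regardless of feature units.
    Fully deterministic for a fixed ``config.seed``.
    """
    if isinstance(features, pd.DataFrame):
        feature_names = tuple(str(c) for c in features.columns)
        X = features.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(features, dtype=np.float64)
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    y_raw = np.asarray(labels)
    classes, y = np.unique(y_raw, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    counts = np.bincount(y)
    if counts.min() < 2:
        rare = classes[counts.argmin()]
        raise ValueError(f"every class needs >= 2 samples; class {rare!r} has {counts.min()}")

    rng = np.random.default_rng(config.seed)
    n, F = X.shape
    model = _init_model(F, len(classes), config, feature_names,
                        [str(c) for c in classes], rng)
    if config.input_scaling == "zscore":
        offset = X.mean(axis=0)
        scale = X.std(axis=0)
    elif config.input_scaling == "minmax":
        offset = X.min(axis=0)
        scale = X.max(axis=0) - offset
    else:
        offset = np.zeros(F)
        scale = np.ones(F)
    scale = np.where(scale == 0, 1.0, scale)
    model.scale_mean, model.scale_std = offset, scale
    Xs = (X - offset) / scale
    Y = np.eye(len(classes))[y]

    lam, alpha = config.selu_lambda, config.selu_alpha
    k = config.n_heads
    p_drop = config.dropout_rate
    params = model._params()
    m_adam = [np.zeros_like(p) for p in params]
    v_adam = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = Xs[idx], Y[idx]
            B = len(idx)

            # forward
            attns, heads = [], []
            for wk, bk in zip(model.w_att, model.b_att):
                a = softmax(xb @ wk.T + bk, axis=1)
                attns.append(a)
                heads.append(xb * a)
            omega = sum(heads) / k
            h1 = omega @ model.w1.T + model.b1
            s = selu(h1, lam, alpha)
            if p_drop > 0:
                mask = (rng.random(s.shape) >= p_drop) / (1.0 - p_drop)
                d = s * mask
            else:
                mask = None
                d = s
            h2 = d @ model.w2.T + model.b2
            g = _sigmoid(h2)
            logits = g @ model.w_out.T + model.b_out
            probs = softmax(logits, axis=1)
            loss = -np.mean(np.log(np.clip((probs * yb).sum(axis=1), 1e-12, None)))
            if not np.isfinite(loss):
                raise FloatingPointError(f"loss became non-finite at epoch {epoch + 1}")
            epoch_loss += loss * B

            # backward
            dlogits = (probs - yb) / B
            d_wout = dlogits.T @ g
            d_bout = dlogits.sum(axis=0)
            dg = dlogits @ model.w_out
            dh2 = dg * g * (1.0 - g)
            d_w2 = dh2.T @ d
            d_b2 = dh2.sum(axis=0)
            dd = dh2 @ model.w2
            ds = dd * mask if mask is not None else dd
            dh1 = ds * _selu_grad(h1, lam, alpha)
            d_w1 = dh1.T @ omega
            d_b1 = dh1.sum(axis=0)
            domega = dh1 @ model.w1
            d_watt, d_batt = [], []
            for a in attns:
                dm = domega / k
                da = dm * xb
                dz = a * (da - (da * a).sum(axis=1, keepdims=True))
                d_watt.append(dz.T @ xb)
                d_batt.append(dz.sum(axis=0))

            grads = [*d_watt, *d_batt, d_w1, d_b1, d_w2, d_b2, d_wout, d_bout]
            step += 1
            for par, grad, m_, v_ in zip(params, grads, m_adam, v_adam):
                m_ += (1 - beta1) * (grad - m_)
                v_ += (1 - beta2) * (grad * grad - v_)
                m_hat = m_ / (1 - beta1 ** step)
                v_hat = v_ / (1 - beta2 ** step)
                par -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        model.loss_trace.append(epoch_loss / n)
    return model


def global_attention(model: AttentionModel) -> AttentionWeights:
    """R_G: softmax of each head's attention-matrix diagonal, averaged over heads."""
    per_head = tuple(softmax(np.diag(wk)) for wk in model.w_att)
    r_g = np.mean(per_head, axis=0)
    return AttentionWeights(r_g=r_g, per_head=per_head, feature_names=model.feature_names)


def fuse_features(F, weights: AttentionWeights, rescale: bool = True):
    """Residual attention reweighting: fused = F + F * (|F| * r_g).

    With ``rescale`` (default) uniform attention doubles every feature,
    which is neutral for threshold-based classifiers; without it the raw
    r_g (summing to 1) is used.  Accepts vectors, matrices or DataFrames
    and preserves the container type.
    """
    r_g = np.asarray(weights.r_g, dtype=np.float64)
    if isinstance(F, pd.DataFrame):
        if F.shape[1] != len(r_g):
            raise ValueError(f"feature count {F.shape[1]} != attention length {len(r_g)}")
        w = len(r_g) * r_g if rescale else r_g
        return F + F * w
    X = np.asarray(F, dtype=np.float64)
    if X.shape[-1] != len(r_g):
        raise ValueError(f"feature count {X.shape[-1]} != attention length {len(r_g)}")
    w = len(r_g) * r_g if rescale else r_g
    return X + X * w
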