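"""Feed-forward Cox proportional-hazards network.

The network maps a covariate vector x to a scalar log-risk h_theta(x);
the hazard is lambda(t | x) = lambda0(t) * exp(h_theta(x)).  Hidden
layers are fully connected with a SELU or ReLU activation followed by
dropout; the output is a single linear node.  Training minimizes the
average negative log Cox partial likelihood

    l(theta) = -(1/N_events) * sum_{i: E_i=1}
               [ h_i - log sum_{j: T_j >= T_i} exp(h_j) ]
               + lambda * sum_l ||W_l||^2

by full-batch gradient descent (the risk-set denominator spans the whole
training set, so minibatching would change the objective).  The learning
rate follows inverse time decay, LR / (1 + epoch * lr_decay), and the
returned model carries the weights that achieved the best validation
concordance index over the epochs.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import SurvivalDataset
from .stats import comparable_pairs, _scored_pairs

__all__ = [
    "NetworkConfig",
    "RiskNetModel",
    "neg_log_partial_likelihood",
    "train",
    "log_risk_mse",
]

# SELU constants (self-normalizing networks)
_SELU_SCALE = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------

def _tie_group_starts(t_sorted: np.ndarray) -> np.ndarray:
    """For ascending-sorted times, the first index of each record's tie group.

    The Breslow risk set of the record at sorted position k is the suffix
    starting at ``starts[k]`` (all records with time >= t_k, ties included).
    """
    n = t_sorted.size
    starts = np.empty(n, dtype=int)
    k = 0
    while k < n:
        j = k
        while j + 1 < n and t_sorted[j + 1] == t_sorted[k]:
            j += 1
        starts[k : j + 1] = k
        k = j + 1
    return starts


def _npll_value_grad(log_risk, time, event):
    """Average negative log partial likelihood and its gradient w.r.t. h.

    Stable evaluation: sort by time, shift by max(h), and take a reversed
    cumulative sum for the risk-set denominators.
    """
    h = np.asarray(log_risk, dtype=float)
    time = np.asarray(time, dtype=float)
    ev = np.asarray(event).astype(bool)
    if not np.isfinite(h).all():
        raise ValueError("log_risk contains NaN or Inf")
    n_events = int(ev.sum())
    if n_events == 0:
        raise ValueError("partial likelihood requires at least one event")

    order = np.argsort(time, kind="stable")
    h_s = h[order]
    ev_s = ev[order]
    starts = _tie_group_starts(time[order])

    m = h_s.max()
    w = np.exp(h_s - m)
    suffix = np.cumsum(w[::-1])[::-1]  # suffix[k] = sum_{j >= k} exp(h_j - m)
    log_denom = m + np.log(suffix[starts])

    value = -(h_s[ev_s] - log_denom[ev_s]).sum() / n_events

    # grad_s[k] = -(1/NE) * (E_k - exp(h_k - m) * P_k),
    # P_k = sum over events i with start(i) <= k of 1 / suffix[start(i)]
    add = np.zeros(h_s.size)
    np.add.at(add, starts[ev_s], 1.0 / suffix[starts[ev_s]])
    P = np.cumsum(add)
    grad_s = -(ev_s.astype(float) - w * P) / n_events
    grad = np.empty_like(grad_s)
    grad[order] = grad_s
    return value, grad


def neg_log_partial_likelihood(log_risk, time, event) -> float:
    """Average negative log Cox partial likelihood of the given log-risks.

    The sum runs over records with an observed event; each term compares
    the record's log-risk with the log-sum-exp over its Breslow risk set
    (all records with observed time >= its own).  The l2 penalty on the
    network weights is *not* included here; the training loop adds it.
    """
    value, _ = _npll_value_grad(log_risk, time, event)
    return value


def log_risk_mse(predicted, true_h, center: bool = True) -> float:
    """Mean squared error between predicted and true log-risks.

    With ``center=True`` (default) both vectors are mean-centered first:
    the log-risk is identifiable only up to an additive constant, so only
    centered comparisons are meaningful across models.
    """
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(true_h, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if center:
        p = p - p.mean()
        t = t - t.mean()
    return float(np.mean((p - t) ** 2))


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Hyper-parameters of the risk network and its training loop.

    ``n_layers`` may be 0, in which case the network is a single linear
    node and the fit reduces to a (gradient-descent) linear Cox model.
    ``momentum`` is the Nesterov momentum for ``sgd_nesterov`` and the
    first-moment constant (beta1) for ``adam``.
    """

    n_layers: int = 1
    n_nodes: int = 8
    activation: str = "selu"
    optimizer: str = "sgd_nesterov"
    learning_rate: float = 1e-3
    lr_decay: float = 0.0
    momentum: float = 0.9
    l2: float = 0.0
    dropout: float = 0.0
    n_epochs: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")
        if self.n_layers > 0 and self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if self.activation not in ("selu", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.optimizer not in ("sgd_nesterov", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.lr_decay < 0:
            raise ValueError("lr_decay must be non-negative")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-feature affine transform learned on the training covariates.

    Continuous columns are shifted/scaled to zero mean and unit SD;
    columns whose training values all lie in {0, 1} (e.g. a treatment
    indicator) pass through unchanged.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        binary = np.array([np.isin(np.unique(col), (0.0, 1.0)).all() for col in X.T])
        mean[binary] = 0.0
        scale[binary] = 1.0
        scale[scale == 0.0] = 1.0  # constant column: pass through
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


# --------------------------------------------------------------------------
# network internals
# --------------------------------------------------------------------------

def _init_weights(d_in: int, config: NetworkConfig, rng: np.random.Generator):
    """Variance-scaling initialization: LeCun-normal for SELU, He for ReLU."""
    gain = 2.0 if config.activation == "relu" else 1.0
    sizes = [d_in] + [config.n_nodes] * config.n_layers + [1]
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        std = np.sqrt(gain / fan_in)
        W = rng.normal(0.0, std, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append([W, b])
    return weights


def _activation(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * np.expm1(z))


def _activation_grad(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(float)
    return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(z))


def _forward(weights, Xs: np.ndarray, config: NetworkConfig,
             rng: np.random.Generator | None = None):
    """Forward pass on standardized input.

    With ``rng`` given, applies inverted dropout after each hidden
    activation (training mode) and returns the caches needed for
    backprop; with ``rng=None`` dropout is off (inference).
    """
    a = Xs
    caches = []
    for li, (W, b) in enumerate(weights[:-1]):
        z = a @ W + b
        act = _activation(z, config.activation)
        if rng is not None and config.dropout > 0.0:
            mask = (rng.random(act.shape) >= config.dropout) / (1.0 - config.dropout)
        else:
            mask = None
        out = act if mask is None else act * mask
        caches.append((a, z, mask))
        a = out
    W, b = weights[-1]
    h = (a @ W + b).ravel()
    caches.append((a, None, None))
    return h, caches


def _backward(weights, caches, dh: np.ndarray, config: NetworkConfig):
    """Backprop of dL/dh through the network; returns per-layer gradients."""
    grads = [None] * len(weights)
    a_last = caches[-1][0]
    delta = dh[:, None]  # (n, 1)
    W_out = weights[-1][0]
    grads[-1] = [a_last.T @ delta, delta.sum(axis=0)]
    da = delta @ W_out.T
    for li in range(len(weights) - 2, -1, -1):
        a_in, z, mask = caches[li]
        if mask is not None:
            da = da * mask
        dz = da * _activation_grad(z, config.activation)
        grads[li] = [a_in.T @ dz, dz.sum(axis=0)]
        da = dz @ weights[li][0].T
    return grads


class _SGDNesterov:
    def __init__(self, weights, momentum):
        self.mu = momentum
        self.v = [[np.zeros_like(W), np.zeros_like(b)] for W, b in weights]

    def step(self, weights, grads, lr):
        for (W, b), (gW, gb), vel in zip(weights, grads, self.v):
            for p, g, j in ((W, gW, 0), (b, gb, 1)):
                vel[j] = self.mu * vel[j] + g
                p -= lr * (g + self.mu * vel[j])


class _Adam:
    def __init__(self, weights, beta1, beta2=0.999, eps=1e-8):
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(W), np.zeros_like(b)] for W, b in weights]
        self.v = [[np.zeros_like(W), np.zeros_like(b)] for W, b in weights]

    def step(self, weights, grads, lr):
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for (W, b), (gW, gb), m, v in zip(weights, grads, self.m, self.v):
            for p, g, j in ((W, gW, 0), (b, gb, 1)):
                m[j] = self.b1 * m[j] + (1 - self.b1) * g
                v[j] = self.b2 * v[j] + (1 - self.b2) * g * g
                p -= lr * (m[j] / c1) / (np.sqrt(v[j] / c2) + self.eps)


# --------------------------------------------------------------------------
# model and training
# --------------------------------------------------------------------------

@dataclass
class RiskNetModel:
    """Trained risk network: weights, input standardizer and training log.

    Prediction is deterministic (dropout is inference-off) and applies
    the standardizer learned on the training set.
    """

    weights: list
    standardizer: Standardizer
    config: NetworkConfig
    feature_names: list[str] = field(default_factory=list)
    training_log: dict = field(default_factory=dict)
    best_epoch: int = -1
    best_val_cindex: float = float("nan")

    def predict_log_risk(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d_in = self.weights[0][0].shape[0]
        if X.shape[1] != d_in:
            raise ValueError(f"X has {X.shape[1]} columns, model expects {d_in}")
        h, _ = _forward(self.weights, self.standardizer.transform(X), self.config)
        return h

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """Serialize weights + standardizer + config as JSON (text format)."""
        payload = {
            "config": self.config.to_dict(),
            "feature_names": self.feature_names,
            "standardizer": {
                "mean": self.standardizer.mean.tolist(),
                "scale": self.standardizer.scale.tolist(),
            },
            "weights": [[W.tolist(), b.tolist()] for W, b in self.weights],
            "best_epoch": self.best_epoch,
            "best_val_cindex": self.best_val_cindex,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "RiskNetModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            weights=[[np.array(W), np.array(b)] for W, b in payload["weights"]],
            standardizer=Standardizer(
                mean=np.array(payload["standardizer"]["mean"]),
                scale=np.array(payload["standardizer"]["scale"]),
            ),
            config=NetworkConfig.from_dict(payload["config"]),
            feature_names=payload["feature_names"],
            best_epoch=payload["best_epoch"],
            best_val_cindex=payload["best_val_cindex"],
        )


def train(
    train_ds: SurvivalDataset,
    val_ds: SurvivalDataset,
    config: NetworkConfig,
) -> RiskNetModel:
    """Train the risk network by full-batch gradient descent.

    The validation concordance index is evaluated every epoch and the
    returned model carries the weights of the best-scoring epoch.  The
    l2 penalty applies to connection weights only, not biases.

    Raises
    ------
    RuntimeError
        If the loss diverges to NaN/Inf (reports the epoch and the last
        finite loss).
    ValueError
        On feature-count mismatch or event-free data.
    """
    if train_ds.d != val_ds.d:
        raise ValueError("train and validation sets have different covariate counts")
    if train_ds.n_events < 1 or val_ds.n_events < 1:
        raise ValueError("training and validation sets must both contain events")

    rng = np.random.default_rng(config.seed)
    standardizer = Standardizer.fit(train_ds.covariates)
    Xtr = standardizer.transform(train_ds.covariates)
    Xva = standardizer.transform(val_ds.covariates)
    weights = _init_weights(train_ds.d, config, rng)

    opt = (
        _Adam(weights, beta1=config.momentum)
        if config.optimizer == "adam"
        else _SGDNesterov(weights, momentum=config.momentum)
    )

    val_pairs = comparable_pairs(val_ds.time, val_ds.event)
    losses = np.empty(config.n_epochs)
    val_ci = np.empty(config.n_epochs)
    best = (-np.inf, -1, None)
    last_finite = np.nan

    for epoch in range(config.n_epochs):
        lr = config.learning_rate / (1.0 + epoch * config.lr_decay)
        h, caches = _forward(weights, Xtr, config, rng=rng)
        if not np.isfinite(h).all():
            raise RuntimeError(
                f"training diverged at epoch {epoch}; last finite loss {last_finite}"
            )
        loss, dh = _npll_value_grad(h, train_ds.time, train_ds.event)
        loss += config.l2 * sum(float((W**2).sum()) for W, _ in weights)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch}; last finite loss {last_finite}"
            )
        last_finite = loss
        grads = _backward(weights, caches, dh, config)
        for (W, _), g in zip(weights, grads):
            g[0] += 2.0 * config.l2 * W
        opt.step(weights, grads, lr)

        h_val, _ = _forward(weights, Xva, config)
        ci = _scored_pairs(h_val, *val_pairs)
        losses[epoch] = loss
        val_ci[epoch] = ci
        if ci > best[0]:
            best = (ci, epoch, copy.deepcopy(weights))

    best_ci, best_epoch, best_weights = best
    return RiskNetModel(
        weights=best_weights if best_weights is not None else weights,
        standardizer=standardizer,
        config=config,
        feature_names=list(train_ds.feature_names),
        training_log={"loss": losses.tolist(), "val_cindex": val_ci.tolist()},
        best_epoch=best_epoch,
        best_val_cindex=float(best_ci),
    )
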