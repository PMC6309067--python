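"""Trainable scoring models.

Both pipeline stages use the same model family: a feed-forward network with
four hidden layers and a sigmoid output unit

    y_hat = sigmoid(W^T X + b) = 1 / (1 + exp(-(W^T X + b)))

trained to minimize the summed negative log likelihood

    L(y, y_hat) = -y log(y_hat) - (1 - y) log(1 - y_hat)

by stochastic gradient descent with momentum and standard back-propagation,
with inverted dropout on the hidden layers for regularization.  Removing the
hidden layers yields the logistic-regression baseline trained by the same
optimizer, used for head-to-head comparison.

The implementation is plain numpy with explicitly seeded initialization and
minibatch shuffling, so identical config + seed reproduces identical
weights.  Analytic gradients are exposed (``loss_and_gradients``) so they
can be checked against finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .rebalance import LabeledDataset

EPS = 1e-12  # prediction clamp before the log-loss

DEFAULT_HIDDEN = (64, 32, 16, 8)


def sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable two-branch form
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TrainConfig:
    """Optimizer and regularization settings for SGD with momentum."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 100
    batch_size: int = 64
    dropout: float = 0.2
    seed: int = 0
    patience: int | None = None  # early stop on training loss plateau

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class ScorerModel:
    """Layered weights/biases; ``hidden_sizes`` empty means plain logistic."""

    input_size: int
    hidden_sizes: tuple[int, ...]
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    activation: str = "relu"
    dropout: float = 0.2
    seed: int = 0

    @property
    def layer_sizes(self) -> list[int]:
        return [self.input_size, *self.hidden_sizes, 1]

    def save(self, path: str | Path) -> None:
        payload = {
            "input_size": self.input_size,
            "hidden_sizes": list(self.hidden_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "activation": self.activation,
            "dropout": self.dropout,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ScorerModel":
        d = json.loads(Path(path).read_text())
        return cls(
            input_size=d["input_size"],
            hidden_sizes=tuple(d["hidden_sizes"]),
            weights=[np.asarray(w) for w in d["weights"]],
            biases=[np.asarray(b) for b in d["biases"]],
            activation=d["activation"],
            dropout=d["dropout"],
            seed=d["seed"],
        )


def init_model(
    input_size: int,
    hidden_sizes: tuple[int, ...] = DEFAULT_HIDDEN,
    dropout: float = 0.2,
    seed: int = 0,
    activation: str = "relu",
) -> ScorerModel:
    """He-style uniform initialization, seeded for reproducibility."""
    rng = np.random.default_rng(seed)
    sizes = [input_size, *hidden_sizes, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return ScorerModel(
        input_size=input_size,
        hidden_sizes=tuple(hidden_sizes),
        weights=weights,
        biases=biases,
        activation=activation,
        dropout=dropout,
        seed=seed,
    )


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {kind!r}")


def _activate_grad(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(float)
    if kind == "tanh":
        return 1.0 - np.tanh(z) ** 2
    raise ValueError(f"unknown activation {kind!r}")


def forward(
    model: ScorerModel,
    x: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Predictions in (0, 1) for a feature row or matrix.

    With ``training=True``, inverted dropout zeroes each hidden unit with
    probability ``model.dropout`` and rescales survivors by 1/(1 - rate);
    inference (``training=False``) is deterministic.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.input_size:
        raise ValueError(f"input width {x.shape[1]} != model input size {model.input_size}")
    preds, _ = _forward_pass(model, x, training, rng)
    return preds


def _forward_pass(model, x, training, rng):
    """Forward pass keeping the per-layer cache needed by back-propagation."""
    if training and model.dropout > 0 and rng is None:
        rng = np.random.default_rng(model.seed)
    a = x
    cache = {"a": [x], "z": [], "drop": []}
    n_hidden = len(model.hidden_sizes)
    for layer, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        cache["z"].append(z)
        if layer < n_hidden:
            a = _activate(z, model.activation)
            if training and model.dropout > 0:
                keep = 1.0 - model.dropout
                mask = (rng.random(a.shape) < keep) / keep
                a = a * mask
                cache["drop"].append(mask)
            else:
                cache["drop"].append(None)
            cache["a"].append(a)
        else:
            # keep outputs strictly inside (0, 1) even when the sigmoid
            # saturates in float arithmetic
            a = np.clip(sigmoid(z), EPS, 1.0 - EPS)
            cache["a"].append(a)
    return a[:, 0], cache


def loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Summed negative log likelihood, with predictions clamped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.clip(np.asarray(y_hat, dtype=float).ravel(), EPS, 1.0 - EPS)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat lengths differ")
    return float(np.sum(-y * np.log(y_hat) - (1.0 - y) * np.log(1.0 - y_hat)))


def loss_and_gradients(
    model: ScorerModel,
    x: np.ndarray,
    y: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
):
    """Summed NLL and its analytic gradients w.r.t. every weight and bias."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    preds, cache = _forward_pass(model, x, training, rng)
    total = loss(y, preds)

    n_hidden = len(model.hidden_sizes)
    grads_W = [np.zeros_like(W) for W in model.weights]
    grads_b = [np.zeros_like(b) for b in model.biases]
    # d(sum NLL)/dz at the sigmoid output is simply (y_hat - y)
    delta = (preds - y)[:, None]
    for layer in range(len(model.weights) - 1, -1, -1):
        a_prev = cache["a"][layer]
        grads_W[layer] = a_prev.T @ delta
        grads_b[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = delta @ model.weights[layer].T
            drop = cache["drop"][layer - 1]
            if drop is not None:
                delta = delta * drop
            delta = delta * _activate_grad(cache["z"][layer - 1], model.activation)
    return total, grads_W, grads_b


def train(
    d: LabeledDataset,
    cfg: TrainConfig,
    hidden_sizes: tuple[int, ...] = DEFAULT_HIDDEN,
    activation: str = "relu",
) -> ScorerModel:
    """Fit a scorer by minibatch SGD with momentum.

    The per-parameter update is ``v <- momentum * v - lr * g;  w <- w + v``
    with ``g`` the batch-mean gradient.  A NaN loss aborts with an error
    naming the epoch.  ``epochs = 0`` returns the seeded initial model.
    """
    X, y = d.features.values, d.labels.astype(float)
    if len(np.unique(d.labels)) < 2:
        raise ValueError("training data must contain both classes")
    model = init_model(
        X.shape[1], hidden_sizes, dropout=cfg.dropout if hidden_sizes else 0.0,
        seed=cfg.seed, activation=activation,
    )
    rng = np.random.default_rng(cfg.seed + 1)
    vel_W = [np.zeros_like(W) for W in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]

    n = X.shape[0]
    best_loss, stall = np.inf, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch_loss, gW, gb = loss_and_gradients(
                model, X[idx], y[idx], training=True, rng=rng
            )
            epoch_loss += batch_loss
            scale = 1.0 / len(idx)
            for layer in range(len(model.weights)):
                vel_W[layer] = cfg.momentum * vel_W[layer] - cfg.learning_rate * gW[layer] * scale
                vel_b[layer] = cfg.momentum * vel_b[layer] - cfg.learning_rate * gb[layer] * scale
                model.weights[layer] += vel_W[layer]
                model.biases[layer] += vel_b[layer]
        if not np.isfinite(epoch_loss):
            raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch + 1}")
        if cfg.patience is not None:
            if epoch_loss < best_loss - 1e-9:
                best_loss, stall = epoch_loss, 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
    return model


def train_logistic(d: LabeledDataset, cfg: TrainConfig) -> ScorerModel:
    """The logistic-regression baseline: the same optimizer, zero hidden layers."""
    cfg = replace(cfg, dropout=0.0)
    return train(d, cfg, hidden_sizes=())
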