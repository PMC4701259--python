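"""From-scratch sigmoid multilayer perceptron trained by backpropagation.

The classifier is deliberately plain: two trainable layers (a hidden layer
of nine sigmoid units and an output layer with one unit per gesture class),
mean-squared-error loss against one-hot targets, constant learning rate
(default 0.01), and early stopping on the test-set error with best-snapshot
restore.  The predicted class is the output unit with maximal activation,
ties broken toward the lowest index.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import FeatureMatrix

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep in practice
    _HAVE_NUMBA = False

__all__ = [
    "MLPModel",
    "TrainingHistory",
    "init_mlp",
    "forward",
    "train",
    "classify",
]


@dataclass
class MLPModel:
    """Layer sizes, weights W[l] (out x in), biases b[l], and the init seed."""

    sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    seed: int

    @property
    def n_inputs(self) -> int:
        return self.sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.sizes[-1]

    def copy(self) -> "MLPModel":
        return MLPModel(
            self.sizes,
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.seed,
        )

    def save(self, path) -> None:
        payload = {
            "sizes": list(self.sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "MLPModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            tuple(payload["sizes"]),
            [np.asarray(w, dtype=np.float64) for w in payload["weights"]],
            [np.asarray(b, dtype=np.float64) for b in payload["biases"]],
            int(payload["seed"]),
        )


@dataclass
class TrainingHistory:
    """Per-epoch train/test errors, the stopping epoch and the best epoch."""

    train_error: list[float] = field(default_factory=list)
    test_error: list[float] = field(default_factory=list)
    stopping_epoch: int = 0
    best_epoch: int = 0
    max_epochs: int = 4000


def init_mlp(sizes: tuple[int, ...], seed: int = 0) -> MLPModel:
    """Seeded uniform U(-0.5, 0.5) weight init, zero biases."""
    if len(sizes) < 2 or any(s < 1 for s in sizes):
        raise ValueError("sizes must be >= 1 with at least input and output layers")
    rng = np.random.default_rng(seed)
    weights = [
        rng.uniform(-0.5, 0.5, size=(sizes[l + 1], sizes[l]))
        for l in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[l + 1]) for l in range(len(sizes) - 1)]
    return MLPModel(tuple(sizes), weights, biases, seed)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def forward_batch(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Outputs for a (n, n_inputs) batch; rows in (0, 1)^n_outputs."""
    A = np.asarray(X, dtype=np.float64)
    if A.ndim != 2 or A.shape[1] != model.n_inputs:
        raise ValueError(f"expected (n, {model.n_inputs}) features, got {A.shape}")
    for W, b in zip(model.weights, model.biases):
        A = _sigmoid(A @ W.T + b)
    return A


def forward(model: MLPModel, features: np.ndarray) -> np.ndarray:
    """Output activations for a single feature vector."""
    features = np.asarray(features, dtype=np.float64)
    if features.shape != (model.n_inputs,):
        raise ValueError(f"expected {model.n_inputs} features, got {features.shape}")
    return forward_batch(model, features[None, :])[0]


def classify(model: MLPModel, features: np.ndarray) -> int:
    """Class = index of the maximal output unit (ties -> lowest index)."""
    return int(np.argmax(forward(model, features)))


def classify_batch(model: MLPModel, X: np.ndarray) -> np.ndarray:
    return np.argmax(forward_batch(model, X), axis=1)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels outside the representable class range")
    T = np.zeros((len(labels), n_classes))
    T[np.arange(len(labels)), labels] = 1.0
    return T


def mse_loss(model: MLPModel, X: np.ndarray, T: np.ndarray) -> float:
    """Mean squared error over samples and output units."""
    O = forward_batch(model, X)
    return float(np.mean((O - T) ** 2))


def loss_and_grads(
    model: MLPModel, X: np.ndarray, T: np.ndarray
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Backpropagation gradients of the MSE loss w.r.t. all weights/biases."""
    activations = [np.asarray(X, dtype=np.float64)]
    for W, b in zip(model.weights, model.biases):
        activations.append(_sigmoid(activations[-1] @ W.T + b))
    O = activations[-1]
    n, k = O.shape
    loss = float(np.mean((O - T) ** 2))
    delta = 2.0 * (O - T) / (n * k) * O * (1.0 - O)
    gW: list[np.ndarray] = [None] * len(model.weights)  # type: ignore[list-item]
    gb: list[np.ndarray] = [None] * len(model.biases)  # type: ignore[list-item]
    for l in range(len(model.weights) - 1, -1, -1):
        gW[l] = delta.T @ activations[l]
        gb[l] = delta.sum(axis=0)
        if l > 0:
            A = activations[l]
            delta = (delta @ model.weights[l]) * A * (1.0 - A)
    return loss, gW, gb


def _online_epoch(
    model: MLPModel, X: np.ndarray, T: np.ndarray, lr: float, order: np.ndarray
) -> None:
    """One shuffled sweep of per-sample gradient updates, in place.

    Each update descends the same per-sample MSE that `loss_and_grads`
    computes for n = 1; the loop is inlined for speed.
    """
    Ws, bs = model.weights, model.biases
    n_layers = len(Ws)
    k = model.n_outputs
    for i in order:
        acts = [X[i]]
        for W, b in zip(Ws, bs):
            acts.append(_sigmoid(W @ acts[-1] + b))
        delta = 2.0 * (acts[-1] - T[i]) / k * acts[-1] * (1.0 - acts[-1])
        for l in range(n_layers - 1, -1, -1):
            gW = np.outer(delta, acts[l])
            gb = delta
            if l > 0:
                delta = (Ws[l].T @ delta) * acts[l] * (1.0 - acts[l])
            Ws[l] -= lr * gW
            bs[l] -= lr * gb


if _HAVE_NUMBA:

    @njit(cache=True)
    def _online_epoch_2layer(W1, b1, W2, b2, X, T, lr, order):  # pragma: no cover
        k = W2.shape[0]
        for idx in order:
            x = X[idx]
            h = 1.0 / (1.0 + np.exp(-(W1 @ x + b1)))
            o = 1.0 / (1.0 + np.exp(-(W2 @ h + b2)))
            delta_o = 2.0 * (o - T[idx]) / k * o * (1.0 - o)
            delta_h = (W2.T @ delta_o) * h * (1.0 - h)
            W2 -= lr * np.outer(delta_o, h)
            b2 -= lr * delta_o
            W1 -= lr * np.outer(delta_h, x)
            b1 -= lr * delta_h


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, FeatureMatrix):
        return data.X, data.labels
    X, y = data
    return np.asarray(X, dtype=np.float64), np.asarray(y, dtype=np.int64)


def train(
    model: MLPModel,
    train_set,
    test_set,
    lr: float = 0.01,
    max_epochs: int = 4000,
    patience: int = 50,
    update: str = "online",
) -> tuple[MLPModel, TrainingHistory]:
    """Gradient-descent backpropagation with test-set early stopping.

    Each epoch is one full sweep of the training set: shuffled per-sample
    updates by default (classical backpropagation, which converges within
    the expected 1000-4000 epochs at lr = 0.01), or a single accumulated
    batch gradient step with ``update="batch"``.  Training stops when the
    test error has not improved for `patience` epochs (or at `max_epochs`);
    the returned model is the snapshot with minimal test error.

    Parameters
    ----------
    train_set, test_set : FeatureMatrix or (X, labels)
        Non-empty feature sets with integer class labels < n_outputs.
    """
    if update not in ("batch", "online"):
        raise ValueError("update must be 'batch' or 'online'")
    Xtr, ytr = _as_xy(train_set)
    Xte, yte = _as_xy(test_set)
    if len(Xtr) == 0 or len(Xte) == 0:
        raise ValueError("train and test sets must be non-empty")
    if Xtr.shape[1] != model.n_inputs or Xte.shape[1] != model.n_inputs:
        raise ValueError("feature width does not match the model input size")
    missing = set(np.unique(yte)) - set(np.unique(ytr))
    if missing:
        warnings.warn(f"classes {sorted(missing)} present in test but absent in train")
    Ttr = one_hot(ytr, model.n_outputs)
    Tte = one_hot(yte, model.n_outputs)

    model = model.copy()
    history = TrainingHistory(max_epochs=max_epochs)
    best = model.copy()
    best_err = np.inf
    since_best = 0
    rng = np.random.default_rng(model.seed + 1)  # online-mode shuffling only

    for epoch in range(max_epochs):
        if update == "batch":
            loss, gW, gb = loss_and_grads(model, Xtr, Ttr)
            for l in range(len(model.weights)):
                model.weights[l] -= lr * gW[l]
                model.biases[l] -= lr * gb[l]
        else:
            order = rng.permutation(len(Xtr))
            if _HAVE_NUMBA and len(model.sizes) == 3:
                _online_epoch_2layer(
                    model.weights[0], model.biases[0],
                    model.weights[1], model.biases[1],
                    Xtr, Ttr, lr, order,
                )
            else:
                _online_epoch(model, Xtr, Ttr, lr, order)
            loss = mse_loss(model, Xtr, Ttr)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged: non-finite loss at epoch {epoch}")
        test_err = mse_loss(model, Xte, Tte)
        history.train_error.append(loss)
        history.test_error.append(test_err)
        if test_err < best_err:
            best_err = test_err
            best = model.copy()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    history.stopping_epoch = len(history.train_error)
    return best, history
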