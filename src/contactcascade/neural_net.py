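"""From-scratch 3-layer feed-forward networks with backpropagation.

The predictor uses small classical nets (one hidden layer, logistic
sigmoid everywhere, one output unit) trained with full-batch gradient
descent plus momentum on binary cross-entropy. Class imbalance between
contacts and non-contacts is handled before training by balanced
sampling, optionally thinned further by a balancing probability factor.

No auto-differentiation dependency: each net is two weight matrices and
two bias vectors, and the gradients are derived by hand (and verified
against central differences in the test suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

FORMAT_TAG = "contactcascade-net-v1"


class NetworkError(ValueError):
    pass


def sigmoid(x: np.ndarray) -> np.ndarray:
    # clip keeps exp() finite; outputs stay strictly inside (0, 1)
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class TrainConfig:
    """Hyperparameters for backpropagation training.

    All values are package defaults — exposed because no single setting
    suits both the 1747-input sub-networks and the 9-input cascade net.
    ``balance_factor`` is the balancing probability factor applied during
    sampling, not here, but is recorded alongside the model.
    """

    learning_rate: float = 0.5
    momentum: float = 0.9
    max_epochs: int = 500
    patience: int = 50
    validation_fraction: float = 0.15
    balance_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise NetworkError("learning_rate must be positive")
        if self.momentum < 0:
            raise NetworkError("momentum must be non-negative")
        if not 0 < self.balance_factor <= 1:
            raise NetworkError("balance_factor must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "momentum": self.momentum,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "validation_fraction": self.validation_fraction,
            "balance_factor": self.balance_factor,
            "seed": self.seed,
        }


@dataclass
class NetworkModel:
    """A 3-layer net: input -> sigmoid hidden -> sigmoid output."""

    layer_sizes: tuple[int, int, int]
    w1: np.ndarray  # (hidden, inputs)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (outputs, hidden)
    b2: np.ndarray  # (outputs,)
    seed: int = 0
    threshold: float = 0.5
    trained: bool = False

    @property
    def n_parameters(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + self.b2.size

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            layer_sizes=self.layer_sizes,
            w1=self.w1.copy(), b1=self.b1.copy(),
            w2=self.w2.copy(), b2=self.b2.copy(),
            seed=self.seed, threshold=self.threshold, trained=self.trained,
        )

    def to_json(self) -> str:
        return json.dumps({
            "format": FORMAT_TAG,
            "layer_sizes": list(self.layer_sizes),
            "activation": "logistic",
            "seed": self.seed,
            "threshold": self.threshold,
            "trained": self.trained,
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "NetworkModel":
        obj = json.loads(text)
        if obj.get("format") != FORMAT_TAG:
            raise NetworkError(f"unknown model format: {obj.get('format')!r}")
        return cls(
            layer_sizes=tuple(obj["layer_sizes"]),
            w1=np.array(obj["w1"], dtype=float),
            b1=np.array(obj["b1"], dtype=float),
            w2=np.array(obj["w2"], dtype=float),
            b2=np.array(obj["b2"], dtype=float),
            seed=int(obj["seed"]),
            threshold=float(obj["threshold"]),
            trained=bool(obj["trained"]),
        )


def init_network(layer_sizes: tuple[int, int, int], seed: int = 0) -> NetworkModel:
    """Initialise weights uniformly in ±1/sqrt(fan_in); reproducible by seed."""
    if len(layer_sizes) != 3 or any(s <= 0 for s in layer_sizes):
        raise NetworkError(f"bad architecture: {layer_sizes}")
    n_in, n_hid, n_out = layer_sizes
    rng = np.random.default_rng(seed)
    lim1 = 1.0 / np.sqrt(n_in)
    lim2 = 1.0 / np.sqrt(n_hid)
    return NetworkModel(
        layer_sizes=tuple(int(s) for s in layer_sizes),
        w1=rng.uniform(-lim1, lim1, size=(n_hid, n_in)),
        b1=rng.uniform(-lim1, lim1, size=n_hid),
        w2=rng.uniform(-lim2, lim2, size=(n_out, n_hid)),
        b2=rng.uniform(-lim2, lim2, size=n_out),
        seed=int(seed),
    )


def forward(model: NetworkModel, x: np.ndarray) -> float | np.ndarray:
    """Network output probability for one input vector or a (P, n_in) batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = x[None, :] if single else x
    if xb.shape[1] != model.layer_sizes[0]:
        raise NetworkError(
            f"bad input width: got {xb.shape[1]}, expected {model.layer_sizes[0]}"
        )
    h = sigmoid(xb @ model.w1.T + model.b1)
    y = sigmoid(h @ model.w2.T + model.b2)[:, 0]
    return float(y[0]) if single else y


def loss_and_gradients(
    model: NetworkModel, x: np.ndarray, y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean binary cross-entropy and its exact gradients for a batch."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    p = x.shape[0]
    h = sigmoid(x @ model.w1.T + model.b1)  # (P, hid)
    out = sigmoid(h @ model.w2.T + model.b2)[:, 0]  # (P,)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(out + eps) + (1 - y) * np.log(1 - out + eps)))
    # dL/dz_out = (out - y)/P for sigmoid + cross-entropy
    dz2 = ((out - y) / p)[:, None]  # (P, 1)
    grads = {
        "w2": dz2.T @ h,
        "b2": dz2.sum(axis=0),
        "w1": None,
        "b1": None,
    }
    dh = dz2 @ model.w2  # (P, hid)
    dz1 = dh * h * (1 - h)
    grads["w1"] = dz1.T @ x
    grads["b1"] = dz1.sum(axis=0)
    return loss, grads


def balanced_sample(
    labels, factor: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Indices of a class-balanced subsample of a binary label list.

    With ``factor`` = 1.0 exactly min(#positives, #negatives) examples of
    each class are drawn (the minority class is kept whole). A factor
    below 1.0 first keeps each positive with that probability, then draws
    an equal number of negatives, thinning the training set symmetrically.
    Output class counts are always exactly equal; order is shuffled but
    reproducible given the seed.
    """
    labels = np.asarray(labels).astype(bool)
    if not 0 < factor <= 1:
        raise NetworkError("factor must be in (0, 1]")
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    if len(pos) == 0 or len(neg) == 0:
        raise NetworkError("cannot balance: a class is absent")
    rng = np.random.default_rng(seed)
    if factor < 1.0:
        pos = pos[rng.random(len(pos)) < factor]
        if len(pos) == 0:  # degenerate thinning: keep one positive
            pos = np.array([rng.choice(np.flatnonzero(labels))])
    n = min(len(pos), len(neg))
    pos = rng.choice(pos, size=n, replace=False)
    neg = rng.choice(neg, size=n, replace=False)
    sel = np.concatenate([pos, neg])
    rng.shuffle(sel)
    return sel


def train(
    model: NetworkModel,
    inputs: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[NetworkModel, list[float]]:
    """Train by full-batch gradient descent with momentum.

    A validation split (deterministic, by config seed) drives early
    stopping with the configured patience; the returned model carries the
    best validation-loss weights. Returns (trained model, per-epoch
    training-loss history).
    """
    config = config or TrainConfig()
    x = np.asarray(inputs, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if x.shape[0] == 0:
        raise NetworkError("no samples")
    if x.shape[0] != y.shape[0]:
        raise NetworkError("inputs and labels differ in count")

    rng = np.random.default_rng(config.seed)
    n = x.shape[0]
    n_val = int(round(n * config.validation_fraction))
    perm = rng.permutation(n)
    val_idx, trn_idx = perm[:n_val], perm[n_val:]
    if len(trn_idx) == 0:
        trn_idx, val_idx = perm, perm[:0]
    xt, yt = x[trn_idx], y[trn_idx]
    xv, yv = x[val_idx], y[val_idx]

    m = model.copy()
    vel = {k: np.zeros_like(getattr(m, k)) for k in ("w1", "b1", "w2", "b2")}
    history: list[float] = []
    best_val = np.inf
    best = m.copy()
    stale = 0
    for _epoch in range(config.max_epochs):
        loss, grads = loss_and_gradients(m, xt, yt)
        history.append(loss)
        for k in vel:
            vel[k] = config.momentum * vel[k] - config.learning_rate * grads[k]
            setattr(m, k, getattr(m, k) + vel[k])
        if len(val_idx) > 0:
            val_loss, _ = loss_and_gradients(m, xv, yv)
            if val_loss < best_val - 1e-9:
                best_val, best, stale = val_loss, m.copy(), 0
            else:
                stale += 1
                if config.patience and stale >= config.patience:
                    break
    trained = best if len(val_idx) > 0 else m
    trained.trained = True
    return trained, history
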