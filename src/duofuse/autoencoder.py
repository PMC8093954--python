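"""Single-hidden-layer autoencoder trained by SGD with momentum.

The encoder maps the (column-wise min-max scaled) input onto a bottleneck;
the decoder reconstructs it; the bottleneck activations are the fused,
reduced feature representation.  Training minimizes mean squared
reconstruction error.

Two hyperparameter profiles ship with the package.  The ``published`` profile
uses 20 epochs, learning rate 0.045, momentum 0.9 and weight decay 0.9 —
the weight decay is unusually large for an L2 coefficient (it shrinks
weights aggressively every step) but is kept as published; the
``practical`` profile replaces it with the conventional 1e-4.  The model
returned carries the parameters of the best epoch by full-batch
reconstruction loss, so the recorded final loss never exceeds the initial
one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np


@dataclass
class AEConfig:
    bottleneck_dim: int | None = None  # default: round(0.3 * input dim)
    epochs: int = 20
    learning_rate: float = 0.045
    momentum: float = 0.9
    weight_decay: float = 0.9
    batch_size: int = 32
    activation: str = "sigmoid"  # 'linear' enables the identity-capable test mode
    allow_full_bottleneck: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation not in ("sigmoid", "linear"):
            raise ValueError("activation must be 'sigmoid' or 'linear'")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def published_profile(cls, **kw) -> "AEConfig":
        return cls(**kw)

    @classmethod
    def practical_profile(cls, **kw) -> "AEConfig":
        kw.setdefault("weight_decay", 1e-4)
        return cls(**kw)


@dataclass
class AEModel:
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    col_min: np.ndarray
    col_range: np.ndarray
    input_dim: int
    bottleneck_dim: int
    activation: str
    initial_loss: float
    final_loss: float

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            for k in ("W1", "b1", "W2", "b2", "col_min", "col_range"):
                f.create_dataset(k, data=getattr(self, k))
            f.attrs.update(
                input_dim=self.input_dim,
                bottleneck_dim=self.bottleneck_dim,
                activation=self.activation,
                initial_loss=self.initial_loss,
                final_loss=self.final_loss,
            )

    @classmethod
    def load(cls, path: str | Path) -> "AEModel":
        with h5py.File(path, "r") as f:
            arrays = {k: f[k][:] for k in ("W1", "b1", "W2", "b2", "col_min", "col_range")}
            return cls(
                **arrays,
                input_dim=int(f.attrs["input_dim"]),
                bottleneck_dim=int(f.attrs["bottleneck_dim"]),
                activation=str(f.attrs["activation"]),
                initial_loss=float(f.attrs["initial_loss"]),
                final_loss=float(f.attrs["final_loss"]),
            )


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    return z


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return a * (1.0 - a)
    return np.ones_like(a)


def _scale(X: np.ndarray, col_min: np.ndarray, col_range: np.ndarray) -> np.ndarray:
    return (X - col_min) / col_range


def train_autoencoder(X: np.ndarray, cfg: AEConfig | None = None) -> AEModel:
    """Fit encoder/decoder weights by minibatch SGDM on reconstruction MSE."""
    cfg = cfg or AEConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("X must be n x D with n >= 2, D >= 1")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    n, D = X.shape
    bottleneck = cfg.bottleneck_dim if cfg.bottleneck_dim is not None else max(1, round(0.3 * D))
    if bottleneck >= D and not cfg.allow_full_bottleneck:
        raise ValueError(f"bottleneck {bottleneck} must be < input dim {D}")
    if bottleneck > D:
        raise ValueError("bottleneck may not exceed the input dim")

    col_min = X.min(axis=0)
    col_range = X.max(axis=0) - col_min
    col_range[col_range == 0] = 1.0
    Xs = _scale(X, col_min, col_range)

    rng = np.random.default_rng(cfg.seed)
    limit1 = np.sqrt(6.0 / (D + bottleneck))
    W1 = rng.uniform(-limit1, limit1, (D, bottleneck))
    b1 = np.zeros(bottleneck)
    W2 = rng.uniform(-limit1, limit1, (bottleneck, D))
    b2 = np.zeros(D)
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)

    def full_loss() -> float:
        H = _act(Xs @ W1 + b1, cfg.activation)
        R = _act(H @ W2 + b2, cfg.activation)
        return float(np.mean((R - Xs) ** 2))

    initial_loss = full_loss()
    best = (initial_loss, W1.copy(), b1.copy(), W2.copy(), b2.copy())

    batch = min(cfg.batch_size, n)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            xb = Xs[idx]
            m = len(idx)
            H = _act(xb @ W1 + b1, cfg.activation)
            R = _act(H @ W2 + b2, cfg.activation)
            # loss gradient averaged over samples, summed over features —
            # keeps the step size independent of the input width
            dR = 2.0 * (R - xb) / m
            dZ2 = dR * _act_grad(R, cfg.activation)
            gW2 = H.T @ dZ2 + cfg.weight_decay * W2
            gb2 = dZ2.sum(axis=0)
            dH = dZ2 @ W2.T
            dZ1 = dH * _act_grad(H, cfg.activation)
            gW1 = xb.T @ dZ1 + cfg.weight_decay * W1
            gb1 = dZ1.sum(axis=0)
            vW1 = cfg.momentum * vW1 - cfg.learning_rate * gW1
            vb1 = cfg.momentum * vb1 - cfg.learning_rate * gb1
            vW2 = cfg.momentum * vW2 - cfg.learning_rate * gW2
            vb2 = cfg.momentum * vb2 - cfg.learning_rate * gb2
            W1 += vW1
            b1 += vb1
            W2 += vW2
            b2 += vb2
        loss = full_loss()
        if loss < best[0]:
            best = (loss, W1.copy(), b1.copy(), W2.copy(), b2.copy())

    final_loss, W1, b1, W2, b2 = best
    return AEModel(
        W1=W1, b1=b1, W2=W2, b2=b2,
        col_min=col_min, col_range=col_range,
        input_dim=D, bottleneck_dim=bottleneck,
        activation=cfg.activation,
        initial_loss=initial_loss, final_loss=final_loss,
    )


def encode(model: AEModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(f"X must have {model.input_dim} columns")
    Xs = _scale(X, model.col_min, model.col_range)
    return _act(Xs @ model.W1 + model.b1, model.activation)


def decode(model: AEModel, H: np.ndarray) -> np.ndarray:
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[1] != model.bottleneck_dim:
        raise ValueError(f"H must have {model.bottleneck_dim} columns")
    Rs = _act(H @ model.W2 + model.b2, model.activation)
    return Rs * model.col_range + model.col_min
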