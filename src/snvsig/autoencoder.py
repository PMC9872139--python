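"""Shallow auto-encoder for feature compression of sparse matrices.

A single hidden layer maps an input ``x`` in ``[0, 1]^p`` to activities
``y = s(Wx + b)`` (ReLU encoder) and back to a reconstruction
``z = h(W'y + b')`` where the decoder activation ``h`` is either sigmoid
(paired with mean cross-entropy loss, suitable when inputs behave like bit
probabilities) or ReLU (paired with mean squared error).  Training minimises
the average reconstruction loss with Adam over seeded, re-shuffled
mini-batches.  The hidden activities are the extracted features passed to
downstream survival modelling.

All numerics are plain NumPy; gradients are exact analytic expressions (and
are verified against central finite differences in the test-suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy.special import expit

__all__ = [
    "AEConfig",
    "AEModel",
    "TrainHistory",
    "minmax_normalize",
    "relu",
    "sigmoid",
    "encode",
    "decode",
    "mce_loss",
    "mse_loss",
    "binary_accuracy",
    "loss_gradients",
    "train",
    "extract_features",
]

_CLIP_EPS = 1e-7  # sigmoid outputs clipped to [eps, 1-eps] inside the MCE


@dataclass
class AEConfig:
    """Architecture and training hyperparameters.

    ``loss="mce"`` requires ``decoder_act="sigmoid"`` so reconstructions lie
    in (0, 1).  Adam moments are fixed at beta1=0.9, beta2=0.999, eps=1e-7.
    """

    p: int
    d: int
    encoder_act: Literal["relu"] = "relu"
    decoder_act: Literal["sigmoid", "relu"] = "sigmoid"
    loss: Literal["mce", "mse"] = "mce"
    tied_weights: bool = False
    learning_rate: float = 0.005
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1 or self.d < 1:
            raise ValueError("p and d must be >= 1")
        if self.encoder_act != "relu":
            raise ValueError("encoder activation must be 'relu'")
        if self.decoder_act not in ("sigmoid", "relu"):
            raise ValueError("decoder activation must be 'sigmoid' or 'relu'")
        if self.loss not in ("mce", "mse"):
            raise ValueError("loss must be 'mce' or 'mse'")
        if self.loss == "mce" and self.decoder_act != "sigmoid":
            raise ValueError("mce loss requires a sigmoid decoder (outputs in (0,1))")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size and epochs must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AEModel:
    """Weights of a trained (or freshly initialised) auto-encoder."""

    W: np.ndarray  # p x d
    b: np.ndarray  # d
    W_out: np.ndarray  # d x p (always W.T when tied)
    b_out: np.ndarray  # p
    config: AEConfig

    def __post_init__(self) -> None:
        p, d = self.config.p, self.config.d
        if self.W.shape != (p, d) or self.b.shape != (d,):
            raise ValueError("encoder weight shapes inconsistent with config")
        if self.W_out.shape != (d, p) or self.b_out.shape != (p,):
            raise ValueError("decoder weight shapes inconsistent with config")
        if self.config.tied_weights:
            self.W_out = self.W.T


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.loss[-1]

    @property
    def final_accuracy(self) -> float:
        return self.accuracy[-1]


def minmax_normalize(X: np.ndarray) -> np.ndarray:
    """Affinely rescale so the global minimum maps to 0 and maximum to 1.

    A 0/1 matrix is returned unchanged; a constant matrix is an error.
    """
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(), X.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant matrix")
    return (X - lo) / (hi - lo)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    return expit(x)


_ACTS = {"relu": relu, "sigmoid": sigmoid}


def encode(model: AEModel, X: np.ndarray) -> np.ndarray:
    """Hidden activities y = s(XW + b); with ReLU these lie in [0, inf)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.config.p:
        raise ValueError(f"expected {model.config.p} input columns, got {X.shape[1]}")
    return _ACTS[model.config.encoder_act](X @ model.W + model.b)


def decode(model: AEModel, Y: np.ndarray) -> np.ndarray:
    """Reconstruction z = h(Y W' + b'); with sigmoid entries lie in (0, 1)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != model.config.d:
        raise ValueError(f"expected {model.config.d} hidden columns, got {Y.shape[1]}")
    W_out = model.W.T if model.config.tied_weights else model.W_out
    return _ACTS[model.config.decoder_act](Y @ W_out + model.b_out)


def mce_loss(X: np.ndarray, Z: np.ndarray) -> float:
    """Mean cross-entropy between inputs and reconstructions.

    The per-sample sum ``-sum_k [x_k log z_k + (1-x_k) log(1-z_k)]`` averaged
    over all n*p entries (framework reduction convention).  Reconstructions
    at exactly 0 or 1 are clipped to ``[1e-7, 1 - 1e-7]``.
    """
    X = np.asarray(X, dtype=float)
    Z = np.clip(np.asarray(Z, dtype=float), _CLIP_EPS, 1.0 - _CLIP_EPS)
    return float(-np.mean(X * np.log(Z) + (1.0 - X) * np.log(1.0 - Z)))


def mse_loss(X: np.ndarray, Z: np.ndarray) -> float:
    """Mean squared error over all entries."""
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    return float(np.mean((X - Z) ** 2))


def binary_accuracy(X: np.ndarray, Z: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of entries where the thresholded reconstruction equals the label.

    ``step(z) = 1`` if ``z > threshold`` else 0; labels that are not exactly
    0 or 1 can never match, so on fractional data this measures the exact-0/1
    content that is reconstructed on the right side of the threshold.
    """
    X = np.asarray(X, dtype=float)
    step = (np.asarray(Z, dtype=float) > threshold).astype(float)
    return float(np.mean(X == step))


def _loss_value(X: np.ndarray, Z: np.ndarray, loss: str) -> float:
    return mce_loss(X, Z) if loss == "mce" else mse_loss(X, Z)


def loss_gradients(model: AEModel, X: np.ndarray):
    """Analytic gradients of the mean reconstruction loss.

    Returns ``(loss, grads)`` where ``grads`` holds ``dW, db, dW_out,
    db_out``.  With tied weights ``dW`` already includes the decoder
    contribution and ``dW_out`` is its transpose view.
    """
    cfg = model.config
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    W_out = model.W.T if cfg.tied_weights else model.W_out

    H = X @ model.W + model.b
    Y = _ACTS[cfg.encoder_act](H)
    Zpre = Y @ W_out + model.b_out
    Z = _ACTS[cfg.decoder_act](Zpre)
    loss = _loss_value(X, Z, cfg.loss)

    scale = 1.0 / (n * p)
    if cfg.loss == "mce":
        # sigmoid + cross-entropy: dL/dZpre collapses to (Z - X) / (n p)
        dZpre = (Z - X) * scale
    else:
        dZ = 2.0 * (Z - X) * scale
        if cfg.decoder_act == "sigmoid":
            dZpre = dZ * Z * (1.0 - Z)
        else:
            dZpre = dZ * (Zpre > 0.0)

    dW_out = Y.T @ dZpre
    db_out = dZpre.sum(axis=0)
    dY = dZpre @ W_out.T
    dH = dY * (H > 0.0)
    dW = X.T @ dH
    db = dH.sum(axis=0)
    if cfg.tied_weights:
        dW = dW + dW_out.T
        dW_out = dW.T
    return loss, {"W": dW, "b": db, "W_out": dW_out, "b_out": db_out}


def _init_model(config: AEConfig) -> AEModel:
    # Glorot-uniform weights, zero biases.
    rng = np.random.default_rng(config.seed)
    lim = np.sqrt(6.0 / (config.p + config.d))
    W = rng.uniform(-lim, lim, size=(config.p, config.d))
    W_out = W.T.copy() if config.tied_weights else rng.uniform(-lim, lim, size=(config.d, config.p))
    return AEModel(
        W=W,
        b=np.zeros(config.d),
        W_out=W_out,
        b_out=np.zeros(config.p),
        config=config,
    )


def train(X: np.ndarray, config: AEConfig) -> tuple[AEModel, TrainHistory]:
    """Train the auto-encoder with Adam over seeded mini-batches.

    Samples are re-shuffled into batches at the start of every epoch (the
    final incomplete batch is kept); after each epoch the loss and binary
    accuracy on the full data are recorded.  Identical data + config give
    identical weights.  A NaN loss aborts with a diagnostic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != config.p:
        raise ValueError(f"X has {X.shape[1]} columns but config.p={config.p}")
    if X.min() < 0.0 or X.max() > 1.0:
        raise ValueError("X must be normalized to [0, 1] before training")

    model = _init_model(config)
    rng = np.random.default_rng(config.seed + 1)
    beta1, beta2, eps = 0.9, 0.999, 1e-7
    params = {"W": model.W, "b": model.b, "W_out": model.W_out, "b_out": model.b_out}
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    history = TrainHistory()
    n = X.shape[0]
    step = 0
    param_keys = ("W", "b", "b_out") if config.tied_weights else ("W", "b", "W_out", "b_out")

    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = X[order[start : start + config.batch_size]]
            loss, grads = loss_gradients(model, batch)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "training loss became non-finite; try a lower learning rate"
                )
            step += 1
            for k in param_keys:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
            if config.tied_weights:
                model.W_out = model.W.T
        Z = decode(model, encode(model, X))
        history.loss.append(_loss_value(X, Z, config.loss))
        history.accuracy.append(binary_accuracy(X, Z))
    return model, history


def extract_features(model: AEModel, X: np.ndarray) -> np.ndarray:
    """Hidden-layer activities used as downstream features.

    Input is min-max normalized first when it falls outside [0, 1] (a 0/1 or
    already-normalized matrix passes through unchanged).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.min() < 0.0 or X.max() > 1.0:
        X = minmax_normalize(X)
    return encode(model, X)


def save_model(model: AEModel, path) -> None:
    """Serialize weights + config to a portable .npz archive."""
    import json

    np.savez(
        path,
        W=model.W,
        b=model.b,
        W_out=model.W_out,
        b_out=model.b_out,
        config=json.dumps(model.config.to_dict()),
    )


def load_model(path) -> AEModel:
    import json

    with np.load(path, allow_pickle=False) as f:
        config = AEConfig(**json.loads(str(f["config"])))
        return AEModel(
            W=f["W"], b=f["b"], W_out=f["W_out"], b_out=f["b_out"], config=config
        )
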