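"""Regression models: partial least squares (PLS1, NIPALS) and a
single-hidden-layer back-propagation neural network.

The PLSR here is the chemometric workhorse for wide, collinear spectral
matrices: latent variables extracted from X'y with deflation of X per
component, collapsed to a single coefficient vector. The BPNN is the
network the metaheuristic optimizers wrap: tanh hidden layer, linear
output, min–max scaling of inputs and targets to [-1, 1], trained by
full-batch gradient descent on MSE in scaled space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


# --------------------------------------------------------------------------
# PLSR
# --------------------------------------------------------------------------

@dataclass
class PLSRModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x k
    x_loadings: np.ndarray  # p x k
    y_loadings: np.ndarray  # k
    coef: np.ndarray  # p

    def to_json(self) -> str:
        return json.dumps({
            "kind": "plsr",
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "coef": self.coef.tolist(),
        })


def plsr_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRModel:
    """PLS1 by NIPALS: per component, weight w ∝ X'y, score t = Xw,
    loadings p = X't/t't and q = y't/t't, then deflate X ← X − t p'.

    The regression vector is B = W (P'W)^{-1} q, so predictions are
    (x − x̄)·B + ȳ.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X row count and y length differ")
    if np.allclose(y, y[0]):
        raise ValueError("y has zero variance")
    k_max = min(n - 1, p)
    if not (1 <= n_components <= k_max):
        raise ValueError(f"n_components must be in [1, {k_max}]")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:  # y residual fully explained
            W, P, q = W[:, :a], P[:, :a], q[:a]
            n_components = a
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-14:
            W, P, q = W[:, :a], P[:, :a], q[:a]
            n_components = a
            break
        pa = Xc.T @ t / tt
        qa = float(yc @ t) / tt
        Xc = Xc - np.outer(t, pa)
        yc = yc - qa * t
        W[:, a], P[:, a], q[a] = w, pa, qa
    if n_components == 0:
        raise ValueError("no usable PLS component (degenerate X)")
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(n_components, x_mean, y_mean, W, P, q, coef)


def plsr_predict(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coef.size:
        raise ValueError("feature count mismatch")
    return (X - model.x_mean) @ model.coef + model.y_mean


def choose_n_components(X: np.ndarray, y: np.ndarray, folds, max_components: int = 20) -> int:
    """Component count with minimum 5-fold RMSECV, capped; ties → fewer."""
    from .evaluation import rmse

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    kmax = min(max_components, min(len(tr) for tr, _ in folds) - 1, X.shape[1])
    best_k, best_err = 1, np.inf
    for k in range(1, kmax + 1):
        preds = np.empty_like(y)
        for tr, te in folds:
            preds[te] = plsr_predict(plsr_fit(X[tr], y[tr], k), X[te])
        err = rmse(y, preds)
        if err < best_err - 1e-12:
            best_k, best_err = k, err
    return best_k


# --------------------------------------------------------------------------
# BPNN
# --------------------------------------------------------------------------

@dataclass
class MinMaxScaler1:
    """Per-feature min–max map onto [-1, 1], fitted on calibration data only."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler1":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lo, hi = X.min(axis=0), X.max(axis=0)
        hi = np.where(hi == lo, lo + 1.0, hi)  # constant feature maps to -1
        return cls(lo, hi)

    def scale(self, X):
        return 2.0 * (np.asarray(X, dtype=float) - self.lo) / (self.hi - self.lo) - 1.0

    def unscale(self, Z):
        return (np.asarray(Z, dtype=float) + 1.0) / 2.0 * (self.hi - self.lo) + self.lo


@dataclass
class TrainConfig:
    epochs: int = 2000
    learning_rate: float = 0.01
    momentum: float = 0.0
    goal: float = 1e-4  # MSE stopping threshold in scaled space
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class BPNNModel:
    n_in: int
    n_hidden: int
    n_out: int
    W1: np.ndarray  # n_hidden x n_in
    b1: np.ndarray  # n_hidden
    W2: np.ndarray  # n_out x n_hidden
    b2: np.ndarray  # n_out
    x_scaler: MinMaxScaler1 | None = None
    y_scaler: MinMaxScaler1 | None = None

    def to_json(self) -> str:
        return json.dumps({
            "kind": "bpnn",
            "shape": [self.n_in, self.n_hidden, self.n_out],
            "theta": weights_to_vector(self).tolist(),
            "x_lo": None if self.x_scaler is None else self.x_scaler.lo.tolist(),
            "x_hi": None if self.x_scaler is None else self.x_scaler.hi.tolist(),
            "y_lo": None if self.y_scaler is None else self.y_scaler.lo.tolist(),
            "y_hi": None if self.y_scaler is None else self.y_scaler.hi.tolist(),
        })


def default_hidden_size(n_in: int, n_out: int = 1) -> int:
    """Conventional sizing heuristic: round(sqrt(n_in + n_out)) + 4."""
    return int(round(np.sqrt(n_in + n_out))) + 4


def bpnn_init(n_in: int, n_hidden: int, n_out: int = 1, seed: int = 0) -> BPNNModel:
    """Weights and thresholds drawn uniformly in [-1, 1]; scalers unfitted."""
    if min(n_in, n_hidden, n_out) < 1:
        raise ValueError("layer sizes must be >= 1")
    rng = np.random.default_rng(seed)
    return BPNNModel(
        n_in, n_hidden, n_out,
        W1=rng.uniform(-1, 1, (n_hidden, n_in)),
        b1=rng.uniform(-1, 1, n_hidden),
        W2=rng.uniform(-1, 1, (n_out, n_hidden)),
        b2=rng.uniform(-1, 1, n_out),
    )


def _forward_scaled(model: BPNNModel, Z: np.ndarray) -> np.ndarray:
    h = np.tanh(Z @ model.W1.T + model.b1)
    return h @ model.W2.T + model.b2


def bpnn_fit_scalers(model: BPNNModel, X: np.ndarray, y: np.ndarray) -> BPNNModel:
    model.x_scaler = MinMaxScaler1.fit(X)
    model.y_scaler = MinMaxScaler1.fit(np.asarray(y, dtype=float).reshape(-1, 1))
    return model


def bpnn_train(model: BPNNModel, X: np.ndarray, y: np.ndarray, cfg: TrainConfig | None = None):
    """Full-batch gradient descent (with momentum) on MSE in scaled space.

    Stops at ``cfg.epochs`` or when MSE falls below ``cfg.goal``. Returns
    ``(model, loss_history)`` with one loss entry per completed epoch.
    """
    cfg = cfg or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    if model.x_scaler is None or model.y_scaler is None:
        bpnn_fit_scalers(model, X, y.ravel())
    Z = model.x_scaler.scale(X)
    T = model.y_scaler.scale(y)
    n = Z.shape[0]
    vel = {k: np.zeros_like(getattr(model, k)) for k in ("W1", "b1", "W2", "b2")}
    history = []
    for _ in range(cfg.epochs):
        H = np.tanh(Z @ model.W1.T + model.b1)
        out = H @ model.W2.T + model.b2
        err = out - T
        loss = float(np.mean(err ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError("BPNN training diverged: non-finite loss")
        history.append(loss)
        if loss < cfg.goal:
            break
        g_out = 2.0 * err / n  # d loss / d out
        grads = {
            "W2": g_out.T @ H,
            "b2": g_out.sum(axis=0),
        }
        g_h = (g_out @ model.W2) * (1.0 - H ** 2)
        grads["W1"] = g_h.T @ Z
        grads["b1"] = g_h.sum(axis=0)
        for k, g in grads.items():
            vel[k] = cfg.momentum * vel[k] - cfg.learning_rate * g
            setattr(model, k, getattr(model, k) + vel[k])
    return model, history


def bpnn_predict(model: BPNNModel, X: np.ndarray) -> np.ndarray:
    """Scale inputs, forward pass, unscale outputs; deterministic."""
    if model.x_scaler is None or model.y_scaler is None:
        raise RuntimeError("model scalers unfitted; train or fit scalers first")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_in:
        raise ValueError("feature count mismatch")
    out = _forward_scaled(model, model.x_scaler.scale(X))
    return model.y_scaler.unscale(out).ravel()


# --------------------------------------------------------------------------
# flat parameter vector <-> network, for the metaheuristic optimizers
# --------------------------------------------------------------------------

def n_parameters(n_in: int, n_hidden: int, n_out: int = 1) -> int:
    return n_hidden * n_in + n_hidden + n_out * n_hidden + n_out


def weights_to_vector(model: BPNNModel) -> np.ndarray:
    """Flatten W1, b1, W2, b2 (row-major, in that order)."""
    return np.concatenate([model.W1.ravel(), model.b1, model.W2.ravel(), model.b2])


def vector_to_weights(theta: np.ndarray, shape: tuple, template: BPNNModel | None = None) -> BPNNModel:
    """Rebuild a network from a flat vector; inverse of :func:`weights_to_vector`.

    ``shape`` is (n_in, n_hidden, n_out); scalers are copied from ``template``.
    """
    n_in, n_hidden, n_out = shape
    theta = np.asarray(theta, dtype=float)
    if theta.size != n_parameters(n_in, n_hidden, n_out):
        raise ValueError(
            f"expected {n_parameters(n_in, n_hidden, n_out)} parameters, got {theta.size}"
        )
    i = 0
    W1 = theta[i:i + n_hidden * n_in].reshape(n_hidden, n_in); i += n_hidden * n_in
    b1 = theta[i:i + n_hidden].copy(); i += n_hidden
    W2 = theta[i:i + n_out * n_hidden].reshape(n_out, n_hidden); i += n_out * n_hidden
    b2 = theta[i:i + n_out].copy()
    return BPNNModel(
        n_in, n_hidden, n_out, W1.copy(), b1, W2.copy(), b2,
        x_scaler=None if template is None else template.x_scaler,
        y_scaler=None if template is None else template.y_scaler,
    )
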