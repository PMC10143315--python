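"""Particle swarm optimization, the sparrow search algorithm, and the
hybrid metaheuristic-initialized BPNN training they enable.

Both optimizers minimize an arbitrary fitness over a box. The hybrid
procedure searches the network's full flattened parameter vector (weights
and thresholds) for the lowest calibration RMSE, then hands the best
vector to gradient back-propagation for fine-tuning — the global search
supplies an initialization that avoids poor local minima.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .regressors import (
    TrainConfig,
    bpnn_fit_scalers,
    bpnn_init,
    bpnn_predict,
    bpnn_train,
    n_parameters,
    vector_to_weights,
    weights_to_vector,
)


@dataclass
class PSOConfig:
    swarm_size: int = 30
    iterations: int = 150
    inertia: tuple = (0.9, 0.4)  # linear decay start -> end
    c1: float = 1.49445
    c2: float = 1.49445
    bounds: tuple = (-1.0, 1.0)  # scalar pair or (dim, 2) array
    v_max_frac: float = 0.2  # max speed as fraction of bound span
    seed: int = 0

    def __post_init__(self):
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("c1, c2 must be > 0")


@dataclass
class SSAConfig:
    population: int = 30
    iterations: int = 150
    producer_fraction: float = 0.2  # PD, discoverers
    scout_fraction: float = 0.2  # SD, danger-aware sparrows
    safety_threshold: float = 0.8  # ST, alarm value
    bounds: tuple = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for f in (self.producer_fraction, self.scout_fraction):
            if not (0 < f < 1):
                raise ValueError("fractions must be in (0, 1)")
        if not (0 < self.safety_threshold <= 1):
            raise ValueError("safety_threshold must be in (0, 1]")


@dataclass
class OptResult:
    best_position: np.ndarray
    best_fitness: float
    history: list  # best-so-far fitness, length iterations + 1
    elapsed: float


def _expand_bounds(bounds, dim):
    b = np.asarray(bounds, dtype=float)
    if b.ndim == 1:
        b = np.tile(b, (dim, 1))
    if b.shape != (dim, 2) or np.any(b[:, 0] >= b[:, 1]):
        raise ValueError("bounds must be per-dimension [low, high] with low < high")
    return b[:, 0], b[:, 1]


def _check_fitness(value, position):
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite fitness at position {position}")
    return float(value)


def pso_minimize(fitness, dim: int, cfg: PSOConfig | None = None) -> OptResult:
    """Canonical global-best PSO with linearly decaying inertia.

    v ← w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x); positions clipped to
    the bounds, velocities to v_max. Returns the best-ever position.
    """
    cfg = cfg or PSOConfig()
    lo, hi = _expand_bounds(cfg.bounds, dim)
    span = hi - lo
    v_max = cfg.v_max_frac * span
    rng = np.random.default_rng(cfg.seed)

    t0 = time.perf_counter()
    X = rng.uniform(lo, hi, (cfg.swarm_size, dim))
    V = rng.uniform(-v_max, v_max, (cfg.swarm_size, dim))
    pbest = X.copy()
    pbest_f = np.array([_check_fitness(fitness(x), x) for x in X])
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    history = [gbest_f]

    w0, w1 = cfg.inertia
    for it in range(cfg.iterations):
        w = w0 + (w1 - w0) * (it / max(cfg.iterations - 1, 1))
        r1 = rng.random((cfg.swarm_size, dim))
        r2 = rng.random((cfg.swarm_size, dim))
        V = np.clip(w * V + cfg.c1 * r1 * (pbest - X) + cfg.c2 * r2 * (gbest - X),
                    -v_max, v_max)
        X = np.clip(X + V, lo, hi)
        f = np.array([_check_fitness(fitness(x), x) for x in X])
        improved = f < pbest_f
        pbest[improved] = X[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        history.append(gbest_f)
    return OptResult(gbest, gbest_f, history, time.perf_counter() - t0)


def ssa_minimize(fitness, dim: int, cfg: SSAConfig | None = None) -> OptResult:
    """Sparrow search: discoverers, joiners and scouts updated in turn.

    Discoverers (the best PD fraction) decay exponentially toward
    exploration while the alarm is quiet (r < ST) and take Gaussian jumps
    otherwise; joiners follow the best discoverer with a random
    binary-weighted displacement, the worse half making long escape jumps;
    a random SD fraction of scouts moves toward the global best, or steps
    away by a bounded random factor when already there.
    """
    cfg = cfg or SSAConfig()
    lo, hi = _expand_bounds(cfg.bounds, dim)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.population
    n_prod = max(1, int(round(cfg.producer_fraction * n)))
    n_scout = max(1, int(round(cfg.scout_fraction * n)))

    t0 = time.perf_counter()
    X = rng.uniform(lo, hi, (n, dim))
    f = np.array([_check_fitness(fitness(x), x) for x in X])
    g = int(np.argmin(f))
    gbest, gbest_f = X[g].copy(), float(f[g])
    history = [gbest_f]

    for it in range(1, cfg.iterations + 1):
        order = np.argsort(f)
        X, f = X[order], f[order]
        worst_x = X[-1].copy()
        # discoverers
        for i in range(n_prod):
            if rng.random() < cfg.safety_threshold:
                alpha = rng.random() or 1e-12
                X[i] = X[i] * np.exp(-(i + 1) / (alpha * cfg.iterations))
            else:
                X[i] = X[i] + rng.normal() * np.ones(dim)
        X[:n_prod] = np.clip(X[:n_prod], lo, hi)
        best_prod = X[int(np.argmin([fitness(x) for x in X[:n_prod]]))].copy()
        # joiners
        for i in range(n_prod, n):
            if i > n / 2:
                X[i] = rng.normal() * np.exp((worst_x - X[i]) / (i + 1) ** 2)
            else:
                A = rng.choice([-1.0, 1.0], size=dim)
                X[i] = best_prod + np.abs(X[i] - best_prod) * A / dim
        X[n_prod:] = np.clip(X[n_prod:], lo, hi)
        f = np.array([_check_fitness(fitness(x), x) for x in X])
        # scouts: a random SD fraction reacts to danger
        scouts = rng.choice(n, size=n_scout, replace=False)
        fbest, fworst = float(f.min()), float(f.max())
        for i in scouts:
            if f[i] > fbest:
                X[i] = gbest + rng.normal(size=dim) * np.abs(X[i] - gbest)
            else:
                K = rng.uniform(-1, 1)
                X[i] = X[i] + K * np.abs(X[i] - worst_x) / (f[i] - fworst + 1e-50)
        X[scouts] = np.clip(X[scouts], lo, hi)
        f[scouts] = [_check_fitness(fitness(X[i]), X[i]) for i in scouts]

        g = int(np.argmin(f))
        if f[g] < gbest_f:
            gbest, gbest_f = X[g].copy(), float(f[g])
        history.append(gbest_f)
    return OptResult(gbest, gbest_f, history, time.perf_counter() - t0)


def hybrid_train(X, y, shape: tuple, method: str = "SSA", opt_cfg=None,
                 train_cfg: TrainConfig | None = None):
    """Metaheuristic-initialized BPNN training (PSO-BP / SSA-BP).

    The fitness of a parameter vector θ is the calibration RMSE of the
    network it encodes (no gradient steps inside the fitness). The
    minimizer's best vector initializes the network; back-propagation
    fine-tunes it. Returns ``(model, OptResult)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n_in, n_hidden, n_out = shape
    train_cfg = train_cfg or TrainConfig()
    method = method.upper()
    if method == "PSO":
        opt_cfg = opt_cfg or PSOConfig(seed=train_cfg.seed)
        minimize = pso_minimize
    elif method == "SSA":
        opt_cfg = opt_cfg or SSAConfig(seed=train_cfg.seed)
        minimize = ssa_minimize
    else:
        raise ValueError(f"unknown metaheuristic {method!r}; expected PSO or SSA")

    template = bpnn_fit_scalers(bpnn_init(n_in, n_hidden, n_out, seed=train_cfg.seed), X, y)
    Z = template.x_scaler.scale(X)
    T = template.y_scaler.scale(y.reshape(-1, 1)).ravel()

    def fitness(theta):
        m = vector_to_weights(theta, shape, template)
        pred = np.tanh(Z @ m.W1.T + m.b1) @ m.W2.T + m.b2
        return float(np.sqrt(np.mean((pred.ravel() - T) ** 2)))

    dim = n_parameters(n_in, n_hidden, n_out)
    if opt_cfg.iterations == 0:
        model, _ = bpnn_train(template, X, y, train_cfg)
        zero = OptResult(weights_to_vector(model), np.nan, [], 0.0)
        return model, zero
    result = minimize(fitness, dim, opt_cfg)
    model = vector_to_weights(result.best_position, shape, template)
    model, _ = bpnn_train(model, X, y, train_cfg)
    return model, result


def bpnn_factory(shape, train_cfg=None, method=None, opt_cfg=None):
    """A model factory (X, y) -> predict for :func:`cross_validate` /
    :func:`evaluate_model`: plain BPNN when ``method`` is None, otherwise
    the PSO/SSA hybrid."""
    def factory(X, y):
        if method is None:
            cfg = train_cfg or TrainConfig()
            model = bpnn_init(*shape, seed=cfg.seed)
            model, _ = bpnn_train(model, X, y, cfg)
        else:
            model, _ = hybrid_train(X, y, shape, method, opt_cfg, train_cfg)
        return lambda Xq: bpnn_predict(model, Xq)
    return factory
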