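"""Dimensionality reduction and wavelength selection: PCA score extraction,
the successive projections algorithm (SPA), and competitive adaptive
reweighted sampling (CARS).

SPA builds chains of minimally collinear channels by repeated orthogonal
projection and scores every (start, length) chain by the cross-validated
RMSE of a multiple linear regression. CARS shrinks the retained channel
set over Monte Carlo runs with an exponential decreasing function and
resamples channels in proportion to the magnitude of their PLS regression
coefficients; the run with the lowest RMSECV wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import make_folds, rmse
from .regressors import plsr_fit, plsr_predict

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray  # p x k_full, orthonormal columns
    explained_ratio: np.ndarray  # fraction of total variance per component
    k: int  # components chosen for downstream modeling

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.explained_ratio)


def pca_fit(X: np.ndarray, variance_target: float | None = 0.95, k: int | None = None) -> PCAModel:
    """Mean-centered SVD; keep the smallest k whose cumulative explained
    variance reaches ``variance_target`` (or an explicit ``k``)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    mean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    var = s ** 2
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    if k is not None:
        if not (1 <= k <= ratio.size):
            raise ValueError(f"k={k} exceeds the {ratio.size} available components")
        chosen = k
    else:
        if not (0 < variance_target <= 1):
            raise ValueError("variance_target must be in (0, 1]")
        chosen = int(np.searchsorted(np.cumsum(ratio), variance_target - 1e-12) + 1)
        chosen = min(chosen, ratio.size)
    return PCAModel(mean, Vt.T, ratio, chosen)


def pca_transform(model: PCAModel, X: np.ndarray, k: int | None = None) -> np.ndarray:
    """Scores (X − mean)·loadings[:, :k]."""
    k = model.k if k is None else k
    if k > model.loadings.shape[1]:
        raise ValueError(f"k={k} exceeds stored components {model.loadings.shape[1]}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.size:
        raise ValueError("channel count mismatch")
    return (X - model.mean) @ model.loadings[:, :k]


# --------------------------------------------------------------------------
# shared
# --------------------------------------------------------------------------

@dataclass
class VariableSubset:
    """Selected channel indices with the method that produced them."""

    indices: tuple  # sorted, unique; empty for PCA
    method: str  # PCA | SPA | CARS
    score: float  # selection criterion (RMSECV)
    n_components: int = 0  # PCA only
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        idx = tuple(sorted(set(int(i) for i in self.indices)))
        if len(idx) != len(self.indices):
            raise ValueError("indices must be unique")
        self.indices = idx

    def fraction_of(self, n_channels: int) -> float:
        """Selected share of the axis, percent."""
        return 100.0 * len(self.indices) / n_channels


def _mlr_rmsecv(X: np.ndarray, y: np.ndarray, folds) -> float:
    """RMSECV of ordinary multiple linear regression (with intercept)."""
    preds = np.empty_like(y)
    for tr, te in folds:
        A = np.column_stack([np.ones(len(tr)), X[tr]])
        beta, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
        preds[te] = np.column_stack([np.ones(len(te)), X[te]]) @ beta
    return rmse(y, preds)


def _pls_rmsecv(X: np.ndarray, y: np.ndarray, folds, n_components: int) -> float:
    preds = np.empty_like(y)
    for tr, te in folds:
        k = min(n_components, len(tr) - 1, X.shape[1])
        preds[te] = plsr_predict(plsr_fit(X[tr], y[tr], k), X[te])
    return rmse(y, preds)


# --------------------------------------------------------------------------
# SPA
# --------------------------------------------------------------------------

def spa_chain(X: np.ndarray, start: int, k_max: int) -> list:
    """Projection chain from one start column: repeatedly project remaining
    columns onto the orthogonal complement of the chosen span and take the
    maximum-norm projection. Returns the ordered chain (length k_max)."""
    R = np.asarray(X, dtype=float).copy()
    p = R.shape[1]
    chain = [start]
    for _ in range(k_max - 1):
        q = R[:, chain[-1]]
        nq = np.linalg.norm(q)
        if nq < 1e-12:
            break
        q = q / nq
        R = R - np.outer(q, q @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] < 1e-10:  # everything left is in the span already
            break
        chain.append(nxt)
    return chain


def spa_select(X: np.ndarray, y: np.ndarray, k_min: int = 1, k_max: int = 10,
               folds=None, starts=None, seed: int = 0) -> VariableSubset:
    """Successive projections algorithm.

    For every candidate start channel, build the projection chain up to
    ``k_max`` and score each prefix of length k in [k_min, k_max] by MLR
    RMSECV on the calibration rows. Minimum RMSECV wins; ties break toward
    smaller k, then lower start index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p == 0 or not np.any(np.linalg.norm(X, axis=0) > 0):
        raise ValueError("degenerate X: no nonzero columns")
    k_max = min(k_max, p, n - 1)
    k_min = max(1, min(k_min, k_max))
    folds = folds if folds is not None else make_folds(y, k=min(5, n), seed=seed)
    starts = range(p) if starts is None else starts

    # center columns as SPA operates on the calibration matrix directly
    best = (np.inf, np.inf, np.inf, None)  # (rmsecv, k, start, subset)
    cache: dict = {}
    for start in starts:
        if np.linalg.norm(X[:, start]) < 1e-12:
            continue
        chain = spa_chain(X, start, k_max)
        for k in range(k_min, min(k_max, len(chain)) + 1):
            subset = tuple(sorted(chain[:k]))
            if subset in cache:
                err = cache[subset]
            else:
                err = _mlr_rmsecv(X[:, subset], y, folds)
                cache[subset] = err
            key = (round(err, 12), k, start)
            if key < best[:3]:
                best = (*key, subset)
    if best[3] is None:
        raise ValueError("SPA found no valid subset")
    return VariableSubset(best[3], "SPA", best[0])


# --------------------------------------------------------------------------
# CARS
# --------------------------------------------------------------------------

def cars_edf_constants(p: int, n_runs: int) -> tuple:
    """Constants of the exponential decreasing function r_i = a·e^(−k·i):
    a = (p/2)^(1/(N−1)), k = ln(p/2)/(N−1), so run 1 keeps all p channels
    and run N keeps 2."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(p / 2.0) / (n_runs - 1)
    return a, k


def cars_select(X: np.ndarray, y: np.ndarray, n_runs: int = 50,
                n_pls_components: int | None = None, folds=None,
                sample_frac: float = 0.8, seed: int = 0) -> VariableSubset:
    """Competitive adaptive reweighted sampling.

    Per run i: fit PLSR on a Monte Carlo draw of the calibration rows over
    the currently retained channels; shrink the retained count to
    round(r_i·p) by a weighted draw without replacement with weights
    |regression coefficient|; record the retained set's 5-fold RMSECV.
    Returns the retained set of the minimum-RMSECV run, with per-run
    diagnostics (retained counts and RMSECV).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 3:
        raise ValueError("CARS needs at least 3 channels")
    rng = np.random.default_rng(seed)
    folds = folds if folds is not None else make_folds(y, k=min(5, n), seed=seed)
    if n_pls_components is None:
        from .regressors import choose_n_components
        n_pls_components = choose_n_components(X, y, folds, max_components=15)

    a, kconst = cars_edf_constants(p, n_runs)
    retained = np.arange(p)
    n_sub = max(2, int(round(sample_frac * n)))
    counts, errors, subsets = [], [], []
    for i in range(1, n_runs + 1):
        rows = rng.choice(n, size=n_sub, replace=False)
        ncomp = min(n_pls_components, retained.size, n_sub - 1)
        if ncomp < n_pls_components:
            logger.info("CARS run %d: components capped at %d", i, ncomp)
        model = plsr_fit(X[np.ix_(rows, retained)], y[rows], ncomp)
        weights = np.abs(model.coef) + 1e-12
        keep = int(round(a * np.exp(-kconst * i) * p))
        keep = max(2, min(keep, retained.size))
        chosen = rng.choice(retained.size, size=keep, replace=False,
                            p=weights / weights.sum())
        retained = np.sort(retained[chosen])
        counts.append(retained.size)
        err = _pls_rmsecv(X[:, retained], y, folds,
                          min(n_pls_components, retained.size))
        errors.append(err)
        subsets.append(retained.copy())
    best = int(np.argmin(np.round(errors, 12)))
    return VariableSubset(
        tuple(subsets[best].tolist()), "CARS", errors[best],
        diagnostics={
            "retained_counts": counts,
            "rmsecv": errors,
            "best_run": best + 1,
            "n_pls_components": n_pls_components,
        },
    )
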