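"""Model evaluation: R², RMSE, RPD, stratified cross-validation, and the
seven-figure performance report (R²c / R²cv / R²p, RMSEC / RMSECV / RMSEP,
RPD) used throughout the calibration literature.

RPD (ratio of performance to deviation) is the sample standard deviation
of the test references divided by RMSEP; > 1.5 reads as a good prediction,
2.0–2.5 satisfactory, > 3.0 a valid quantitative model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np


def r_squared(y_true, y_pred, kind: str = "determination") -> float:
    """Coefficient of determination 1 − SS_res/SS_tot (default), or the
    squared Pearson correlation with ``kind='pearson'``."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y_true is constant; R^2 undefined")
    if kind == "pearson":
        return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("need nonempty equal-length vectors")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def rpd(y_true_test, rmsep: float) -> float:
    """sd(test references, ddof=1) / RMSEP."""
    y = np.asarray(y_true_test, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("RPD needs at least 2 test values")
    if rmsep == 0:
        warnings.warn("RMSEP is 0; RPD reported as infinite")
        return float("inf")
    if rmsep < 0:
        raise ValueError("rmsep must be >= 0")
    return float(np.std(y, ddof=1) / rmsep)


def rpd_label(value: float) -> str:
    """Qualitative reading of an RPD value."""
    if value > 3.0:
        return "valid"
    if value >= 2.0:
        return "satisfactory"
    if value > 1.5:
        return "good"
    return "poor"


@dataclass(frozen=True)
class FoldSpec:
    """k near-equal folds, stratified by a grouping label (concentration group)."""

    k: int
    assignments: tuple  # row index -> fold id
    seed: int

    def folds(self):
        a = np.asarray(self.assignments)
        return [(np.flatnonzero(a != f), np.flatnonzero(a == f)) for f in range(self.k)]


def make_folds(strata, k: int = 5, seed: int = 0):
    """Stratified fold index pairs [(train_idx, test_idx), ...].

    Rows sharing a stratum value (e.g. gradient group, or quantized y) are
    shuffled and dealt round-robin across folds, so every fold sees every
    concentration level where possible.
    """
    strata = np.asarray(strata)
    n = strata.size
    if k < 2 or k > n:
        raise ValueError(f"fold count {k} infeasible for {n} rows")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=int)
    offset = 0
    # quantize continuous strata so each bin groups similar values
    if strata.dtype.kind == "f" and np.unique(strata).size > 20:
        strata = np.digitize(strata, np.quantile(strata, np.linspace(0, 1, 9)[1:-1]))
    for val in np.unique(strata):
        idx = np.flatnonzero(strata == val)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            assignments[i] = (offset + j) % k
        offset += idx.size
    return FoldSpec(k, tuple(assignments.tolist()), seed).folds()


def cross_validate(model_factory, X, y, folds):
    """Out-of-fold metrics: fit ``model_factory(X_tr, y_tr) -> predict_fn``
    inside each fold, concatenate held-out predictions, compute R²cv /
    RMSECV once on the full out-of-fold vector."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    preds = np.empty_like(y)
    for fi, (tr, te) in enumerate(folds):
        if len(tr) == 0 or len(te) == 0:
            raise ValueError(f"fold {fi} is empty")
        try:
            predict = model_factory(X[tr], y[tr])
        except Exception as exc:
            raise RuntimeError(f"model factory failed in fold {fi}: {exc}") from exc
        preds[te] = predict(X[te])
    return r_squared(y, preds), rmse(y, preds)


@dataclass
class PerformanceReport:
    """The full seven-metric report for one (element, model) combination."""

    element: str
    model_name: str
    n_variables: int
    R2_c: float
    R2_cv: float
    R2_p: float
    RMSEC: float
    RMSECV: float
    RMSEP: float
    RPD: float
    duration: float = 0.0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def label(self) -> str:
        return rpd_label(self.RPD)

    def to_dict(self, ndigits: int | None = None) -> dict:
        d = asdict(self)
        if ndigits is not None:
            for k, v in d.items():
                if isinstance(v, float):
                    d[k] = round(v, ndigits)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def evaluate_model(model_factory, X_train, y_train, X_test, y_test, folds,
                   element: str = "", model_name: str = "", n_variables: int = 0,
                   duration: float = 0.0, seed: int = 0,
                   train_ids=None, test_ids=None) -> PerformanceReport:
    """Fit on the training partition and fill the full report.

    R²c/RMSEC on the training fit, R²cv/RMSECV by refitting inside each
    fold, R²p/RMSEP on the test partition, RPD from the test references.
    Aborts if any sample id appears in both partitions.
    """
    if train_ids is not None and test_ids is not None:
        shared = set(train_ids) & set(test_ids)
        if shared:
            raise ValueError(f"train/test leakage: shared sample ids {sorted(shared)[:5]}")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_test = np.asarray(y_test, dtype=float).ravel()

    predict = model_factory(X_train, y_train)
    r2_c = r_squared(y_train, predict(X_train))
    rmsec = rmse(y_train, predict(X_train))
    r2_cv, rmsecv = cross_validate(model_factory, X_train, y_train, folds)
    pred_test = predict(X_test)
    rmsep = rmse(y_test, pred_test)
    return PerformanceReport(
        element=element, model_name=model_name,
        n_variables=n_variables or X_train.shape[1],
        R2_c=r2_c, R2_cv=r2_cv, R2_p=r_squared(y_test, pred_test),
        RMSEC=rmsec, RMSECV=rmsecv, RMSEP=rmsep,
        RPD=rpd(y_test, rmsep), duration=duration, seed=seed,
    )
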