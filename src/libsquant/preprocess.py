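"""Spectral pretreatments (MSC, SNV, wavelet denoising, Savitzky–Golay)
and the cross-validated selection among them.

All transforms are row-wise: each spectrum is corrected independently
(MSC against a reference learned from calibration rows only). Method
comparison mirrors the standard chemometric workflow: apply each
pretreatment inside every cross-validation fold, fit a PLSR model, and
keep the method with the lowest RMSECV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)

#: tie-break order, simplest first
METHOD_SIMPLICITY = ("none", "SNV", "SG", "WT", "MSC")


def msc(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row is regressed on the reference, x_i ≈ a_i + b_i·ref, and the
    affine distortion inverted: (x_i − a_i)/b_i. Rows with |b_i| < 1e-12
    are returned unchanged with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = np.asarray(reference, dtype=float)
    if ref.shape[0] != X.shape[1]:
        raise ValueError("reference length must match channel count")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0.0:
        raise ValueError("MSC reference must not be constant")
    row_means = X.mean(axis=1)
    b = (X - row_means[:, None]) @ ref_c / denom
    a = row_means - b * ref.mean()
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        if abs(b[i]) < 1e-12:
            logger.warning("MSC: row %d has near-zero slope; returned unchanged", i)
            out[i] = X[i]
        else:
            out[i] = (X[i] - a[i]) / b[i]
    return out


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-row centering and scaling to unit sd (ddof=1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least 2 channels per row")
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"SNV: constant row(s) {bad.tolist()} have zero spread")
    return (X - X.mean(axis=1)[:, None]) / sd[:, None]


def sg_smooth(X: np.ndarray, window: int = 9, polyorder: int = 3) -> np.ndarray:
    """Savitzky–Golay smoothing per row; edges by polynomial extrapolation."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if window > X.shape[1]:
        raise ValueError("window exceeds channel count")
    return savgol_filter(X, window_length=window, polyorder=polyorder, axis=1, mode="interp")


def wt_denoise(X: np.ndarray, wavelet: str = "db4", level: int = 3, mode: str = "soft",
               threshold: float | None = None) -> np.ndarray:
    """Wavelet shrinkage denoising per row.

    Multilevel DWT; detail coefficients shrunk with the universal threshold
    t = σ̂·sqrt(2·ln n), σ̂ = median(|finest detail|)/0.6745 (or an explicit
    ``threshold``); reconstruction truncated back to the input length.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[1]
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if level < 1 or level > max_level:
        raise ValueError(f"level {level} infeasible for {n} channels with {wavelet} (max {max_level})")
    out = np.empty_like(X)
    for i, row in enumerate(X):
        coeffs = pywt.wavedec(row, wavelet, level=level)
        if threshold is None:
            finest = coeffs[-1]
            sigma = np.median(np.abs(finest)) / 0.6745 if finest.size else 0.0
            t = sigma * np.sqrt(2.0 * np.log(n))
        else:
            t = threshold
        if t > 0:
            den = [coeffs[0]] + [pywt.threshold(c, t, mode=mode) for c in coeffs[1:]]
        else:
            den = coeffs
        out[i] = pywt.waverec(den, wavelet)[:n]
    return out


@dataclass
class PreprocessMethod:
    """A named pretreatment with its parameters and (for MSC) fitted state."""

    name: str
    params: dict = field(default_factory=dict)
    fitted_state: np.ndarray | None = None  # MSC reference spectrum

    _DEFAULTS = {
        "none": {},
        "MSC": {},
        "SNV": {},
        "SG": {"window": 9, "polyorder": 3},
        "WT": {"wavelet": "db4", "level": 3, "mode": "soft"},
    }

    def __post_init__(self):
        if self.name not in self._DEFAULTS:
            raise ValueError(f"unknown preprocessing method {self.name!r}")
        merged = dict(self._DEFAULTS[self.name])
        merged.update(self.params)
        self.params = merged

    def fit(self, X_cal: np.ndarray) -> "PreprocessMethod":
        """Learn any state from calibration rows (MSC: mean calibration spectrum)."""
        if self.name == "MSC":
            self.fitted_state = np.atleast_2d(np.asarray(X_cal, dtype=float)).mean(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.name == "none":
            return np.atleast_2d(np.asarray(X, dtype=float)).copy()
        if self.name == "MSC":
            if self.fitted_state is None:
                raise RuntimeError("MSC must be fitted before transform")
            return msc(X, self.fitted_state)
        if self.name == "SNV":
            return snv(X)
        if self.name == "SG":
            return sg_smooth(X, **self.params)
        return wt_denoise(X, **self.params)

    def fit_transform(self, X_cal: np.ndarray) -> np.ndarray:
        return self.fit(X_cal).transform(X_cal)


def select_preprocessing(X: np.ndarray, y: np.ndarray, methods=None, folds=None,
                         n_components: int = 10, seed: int = 0):
    """Pick the pretreatment whose PLSR model has the lowest RMSECV.

    Every method is applied inside each fold with its state (MSC reference)
    learned from the fold's training rows only — the held-out rows never
    leak into the fit. Ties are broken toward the simpler method
    (none < SNV < SG < WT < MSC).

    Returns ``(best: PreprocessMethod fitted on all of X, table)`` where
    ``table`` maps method name -> {"R2_cv": ..., "RMSECV": ...}.
    """
    from .evaluation import make_folds, r_squared, rmse
    from .regressors import plsr_fit, plsr_predict

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if methods is None:
        methods = list(METHOD_SIMPLICITY)
    if not methods:
        raise ValueError("at least one method required")
    folds = folds if folds is not None else make_folds(y, k=5, seed=seed)
    if any(len(te) == 0 or len(tr) == 0 for tr, te in folds):
        raise ValueError("cross-validation infeasible: empty fold")

    table = {}
    for name in methods:
        preds = np.empty_like(y)
        for tr, te in folds:
            method = PreprocessMethod(name).fit(X[tr])
            Xtr, Xte = method.transform(X[tr]), method.transform(X[te])
            k = min(n_components, len(tr) - 1, Xtr.shape[1])
            model = plsr_fit(Xtr, y[tr], k)
            preds[te] = plsr_predict(model, Xte)
        table[name] = {"R2_cv": r_squared(y, preds), "RMSECV": rmse(y, preds)}

    order = {m: i for i, m in enumerate(METHOD_SIMPLICITY)}
    best_name = min(table, key=lambda m: (round(table[m]["RMSECV"], 12), order.get(m, 99)))
    return PreprocessMethod(best_name).fit(X), table
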