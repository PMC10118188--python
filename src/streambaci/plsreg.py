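"""Centered/scaled univariate PLS regression with leave-one-out validation.

The fit uses the SIMPLS algorithm (deterministic; identical to NIPALS for a
single response).  Both regressors and response are centered and scaled to
unit standard deviation (ddof=1) before fitting; predictions are mapped back
to the input response scale through the stored means and scales.

Model quality is judged by full leave-one-out cross-validation: each
observation is predicted from a model fit without it, with centering and
scaling re-estimated inside every fold.  RMSECV and R2CV are computed from
the pooled held-out predictions; R2CV may be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Scaler",
    "PlsFit",
    "CvCurves",
    "center_scale",
    "fit_pls",
    "predict",
    "loo_cv",
    "select_k",
]

_RANK_TOL = 1e-10


@dataclass
class Scaler:
    """Stored column means/scales for regressors and response."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    constant_cols: np.ndarray  # boolean flags for zero-variance columns

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_scale

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_scale

    def inverse_x(self, Xs: np.ndarray) -> np.ndarray:
        return Xs * self.x_scale + self.x_mean

    def inverse_y(self, ys: np.ndarray) -> np.ndarray:
        return ys * self.y_scale + self.y_mean


def center_scale(X, y, on_constant: str = "error"):
    """Center and scale columns of ``X`` and ``y`` to mean 0, sd 1 (ddof=1).

    Parameters
    ----------
    on_constant : "error" | "zero"
        What to do with a zero-variance column: raise naming the column,
        or keep it (it becomes an all-zero column with scale set to 1 so
        it carries no information).  A zero-variance response always
        raises.

    Returns
    -------
    (Xs, ys, scaler)
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    constant = x_sd <= 0
    if constant.any():
        if on_constant == "error":
            idx = np.flatnonzero(constant)
            raise ValueError(f"zero-variance regressor column(s) at index {idx.tolist()}")
        x_sd = np.where(constant, 1.0, x_sd)
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1))
    if y_sd <= 0:
        raise ValueError("zero-variance response")
    scaler = Scaler(x_mean=x_mean, x_scale=x_sd, y_mean=y_mean, y_scale=y_sd, constant_cols=constant)
    return scaler.transform_x(X), scaler.transform_y(y), scaler


@dataclass
class PlsFit:
    """A SIMPLS fit on centered/scaled data, with raw-scale coefficients.

    ``coef_std`` lives on the standardized (centered/scaled) scale;
    ``coef_raw`` and ``intercept_raw`` reproduce predictions on the scale
    of the inputs passed to :func:`fit_pls`.
    """

    k: int
    scaler: Scaler
    weights: np.ndarray  # R, (p, k): Xs @ R = T
    scores: np.ndarray  # T, (n, k), orthonormal
    loadings: np.ndarray  # P, (p, k)
    q: np.ndarray  # (k,), response loadings per component
    coef_std: np.ndarray
    coef_raw: np.ndarray
    intercept_raw: float
    fitted: np.ndarray  # on raw scale
    residuals: np.ndarray  # on raw scale
    r2: float
    r2_per_k: np.ndarray = field(repr=False, default=None)

    def predict(self, Xnew) -> np.ndarray:
        Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
        return self.intercept_raw + Xnew @ self.coef_raw


def _simpls(Xs: np.ndarray, ys: np.ndarray, k: int):
    """SIMPLS core on standardized data.

    Returns (R, T, P, q) with orthonormal scores T.  Raises if a requested
    component exceeds the effective rank of ``Xs``.
    """
    n, p = Xs.shape
    s = Xs.T @ ys
    R = np.zeros((p, k))
    T = np.zeros((n, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    V = np.zeros((p, k))
    base = float(np.linalg.norm(Xs.T @ ys)) or 1.0
    for a in range(k):
        r = s.copy()
        t = Xs @ r
        tnorm = float(np.linalg.norm(t))
        if tnorm <= _RANK_TOL * max(1.0, base):
            raise ValueError(
                f"component {a + 1} exceeds the rank of X (requested k={k})"
            )
        t /= tnorm
        r /= tnorm
        pvec = Xs.T @ t
        q[a] = float(ys @ t)
        v = pvec.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pvec)
        vnorm = float(np.linalg.norm(v))
        if vnorm > 0:
            v /= vnorm
        V[:, a] = v
        s = s - v * (v @ s)
        R[:, a] = r
        T[:, a] = t
        P[:, a] = pvec
    return R, T, P, q


def fit_pls(X, y, k: int) -> PlsFit:
    """Fit a k-component univariate PLS model.

    ``X`` may be a :class:`~streambaci.design.DesignMatrix` or an array.
    Centering/scaling is estimated here and stored; fitted values and
    residuals are returned on the input scale of ``y``.
    """
    X = getattr(X, "X", X)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the number of regressor columns ({X.shape[1]})")
    Xs, ys, scaler = center_scale(X, y, on_constant="zero")
    R, T, P, q = _simpls(Xs, ys, k)
    coef_std = R @ q
    coef_raw = coef_std * (scaler.y_scale / scaler.x_scale)
    coef_raw = np.where(scaler.constant_cols, 0.0, coef_raw)
    intercept = scaler.y_mean - float(scaler.x_mean @ coef_raw)
    fitted = intercept + X @ coef_raw
    resid = y - fitted
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2_per_k = np.cumsum(q**2) / float(ys @ ys)
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return PlsFit(
        k=k,
        scaler=scaler,
        weights=R,
        scores=T,
        loadings=P,
        q=q,
        coef_std=coef_std,
        coef_raw=coef_raw,
        intercept_raw=intercept,
        fitted=fitted,
        residuals=resid,
        r2=r2,
        r2_per_k=r2_per_k,
    )


def predict(fit: PlsFit, Xnew) -> np.ndarray:
    return fit.predict(Xnew)


@dataclass
class CvCurves:
    """Pooled leave-one-out error curves over k = 1..k_max."""

    rmsecv: np.ndarray
    r2cv: np.ndarray
    predictions: np.ndarray  # (n, k_max) held-out predictions, raw y scale
    flagged_folds: list  # folds where a zero-variance column appeared


def loo_cv(X, y, k_max: int) -> CvCurves:
    """Full leave-one-out cross-validation of the PLS fit.

    Each fold re-estimates centering/scaling.  A fold in which a dummy
    column loses all its variance is still predicted (the column drops
    out) but the fold index is flagged.
    """
    X = getattr(X, "X", X)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("leave-one-out needs n >= 3")
    k_max = int(min(k_max, p))
    preds = np.full((n, k_max), np.nan)
    flagged: list[int] = []
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        Xi, yi = X[mask], y[mask]
        Xs, ys, scaler = center_scale(Xi, yi, on_constant="zero")
        if scaler.constant_cols.any():
            flagged.append(i)
        k_eff = k_max
        while k_eff >= 1:
            try:
                R, T, P, q = _simpls(Xs, ys, k_eff)
                break
            except ValueError:
                k_eff -= 1
        if k_eff < 1:
            preds[i, :] = yi.mean()
            continue
        x0 = (X[i] - scaler.x_mean) / scaler.x_scale
        contrib = (x0 @ R) * q * scaler.y_scale  # per-component contribution
        cum = scaler.y_mean + np.cumsum(contrib)
        preds[i, :k_eff] = cum
        if k_eff < k_max:
            preds[i, k_eff:] = cum[-1]
    errs = y[:, None] - preds
    rmsecv = np.sqrt(np.nanmean(errs**2, axis=0))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    press = np.nansum(errs**2, axis=0)
    r2cv = 1.0 - press / ss_tot if ss_tot > 0 else np.full(k_max, -np.inf)
    return CvCurves(rmsecv=rmsecv, r2cv=r2cv, predictions=preds, flagged_folds=flagged)


def select_k(rmsecv_curve, tau: float = 0.02) -> int:
    """Pick the number of latent variables from an RMSECV curve.

    The smallest k at which the relative improvement from k to k+1 drops
    to ``tau`` or below, capped at the k of the global minimum.  A
    length-1 curve returns 1.
    """
    curve = np.asarray(rmsecv_curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty RMSECV curve")
    if curve.size == 1:
        return 1
    k_min = int(np.argmin(curve)) + 1
    tol = 1e-9
    for k in range(1, curve.size):
        prev = curve[k - 1]
        improvement = (prev - curve[k]) / prev if prev > 0 else 0.0
        if improvement <= tau + tol:
            return min(k, k_min)
    return k_min
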