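"""Degrees of freedom of a PLS fit via the derivative of the fitted values.

For a univariate PLS fit on centered data the fitted values are
``yhat = T T' y`` with ``T`` an orthonormal basis of the Krylov space
spanned by ``{X X'y, X (X'X) X'y, ...}``.  Because ``T`` itself depends on
``y``, the effective degrees of freedom exceed the component count; they
equal ``1 + trace(d yhat / d y)`` with the trace taken analytically by
propagating derivatives through the Krylov recursion and its
Gram-Schmidt orthonormalization.

The same linearized operator supplies leverage values for the
heteroscedasticity-robust resampling schemes.
"""

from __future__ import annotations

import warnings

import numpy as np

from .plsreg import center_scale

__all__ = ["pls_dof", "linearized_hat", "leverage"]

_COND_TOL = 1e-10


class DofConditioningWarning(UserWarning):
    """Raised when the Krylov basis is numerically near-singular."""


def _krylov_with_derivatives(Xs: np.ndarray, yc: np.ndarray, k: int):
    """Orthonormal score basis T and the derivatives dT_i = d t_i / d y.

    ``Xs``: standardized regressors (n x p); ``yc``: centered response.
    Returns (T, dTs, ill_conditioned).
    """
    n, p = Xs.shape
    A = Xs.T @ Xs
    b = Xs.T @ yc
    db = Xs.T.copy()  # d b / d y  (p x n)

    # raw Krylov vectors in score space: v_i = Xs A^{i-1} b
    raw_v = []
    raw_dv = []
    c, dc = b, db
    for _ in range(k):
        raw_v.append(Xs @ c)
        raw_dv.append(Xs @ dc)
        c = A @ c
        dc = A @ dc

    T = np.zeros((n, k))
    dTs = []
    ill = False
    for i in range(k):
        w = raw_v[i].copy()
        dw = raw_dv[i].copy()
        for j in range(i):
            tj = T[:, j]
            dtj = dTs[j]
            s = float(tj @ w)
            ds = w @ dtj + tj @ dw  # row vector (n,)
            dw = dw - np.outer(tj, ds) - dtj * s
            w = w - tj * s
        nrm = float(np.linalg.norm(w))
        scale = float(np.linalg.norm(raw_v[i])) or 1.0
        if nrm <= _COND_TOL * scale:
            ill = True
            warnings.warn(
                f"Krylov basis nearly singular at component {i + 1}",
                DofConditioningWarning,
            )
            if nrm == 0:
                nrm = 1.0
        dnrm = (w @ dw) / nrm  # (n,)
        t = w / nrm
        dt = dw / nrm - np.outer(w, dnrm) / nrm**2
        T[:, i] = t
        dTs.append(dt)
    return T, dTs, ill


def _centered_jacobian(Xs: np.ndarray, yc: np.ndarray, k: int):
    """Jacobian of the centered fitted values w.r.t. the centered response."""
    n = Xs.shape[0]
    T, dTs, ill = _krylov_with_derivatives(Xs, yc, k)
    J = T @ T.T
    for i in range(k):
        ti = T[:, i]
        dti = dTs[i]
        si = float(ti @ yc)
        J = J + dti * si + np.outer(ti, yc @ dti)
    return J, ill


def pls_dof(X, y, k: int) -> float:
    """Effective degrees of freedom of the k-component PLS fit.

    ``1 + trace(d yhat / d y)`` on the centered scale; the leading 1
    accounts for the estimated intercept (mean).  At ``k = rank(X)`` this
    equals ``p + 1``, the least-squares value.  The result is clipped to
    ``[1, n]``.
    """
    X = getattr(X, "X", X)
    Xs, ys, scaler = center_scale(X, y, on_constant="zero")
    yc = np.asarray(y, dtype=float).ravel() - float(np.mean(y))
    # fitted values are invariant to the response scaling, so work with yc
    J, _ = _centered_jacobian(Xs, yc, k)
    dof = 1.0 + float(np.trace(J))
    n = Xs.shape[0]
    return float(np.clip(dof, 1.0, n))


def linearized_hat(X, y, k: int) -> np.ndarray:
    """Full linearized hat operator including the centering term.

    At ``k = rank(X)`` this reduces to the ordinary least-squares hat
    matrix with intercept.
    """
    X = getattr(X, "X", X)
    Xs, ys, scaler = center_scale(X, y, on_constant="zero")
    y = np.asarray(y, dtype=float).ravel()
    yc = y - float(y.mean())
    n = Xs.shape[0]
    J, _ = _centered_jacobian(Xs, yc, k)
    C = np.eye(n) - np.ones((n, n)) / n
    return np.ones((n, n)) / n + J @ C


def leverage(X, y, k: int) -> np.ndarray:
    """Diagonal of the linearized hat operator, clipped to [0, 1)."""
    h = np.diag(linearized_hat(X, y, k)).copy()
    n = h.shape[0]
    hi_cap = 1.0 - 1e-8
    if np.any(h >= hi_cap):
        warnings.warn("leverage value(s) at or above 1 were capped", UserWarning)
    return np.clip(h, 0.0, hi_cap)
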