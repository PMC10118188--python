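"""Box-Cox response transformation chosen by cross-validated model quality.

The transform exponent is selected to maximize R2CV of the PLS model fit to
the transformed response, not by likelihood.  A dense exponent grid is the
reference search; a small genetic-algorithm optimizer over the same range is
available as an alternative.  The identity transform (lambda = 1, shift = 0)
is retained unless a candidate beats it by more than ``min_gain``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import boxcox as _boxcox, inv_boxcox as _inv_boxcox

from .plsreg import loo_cv, select_k

__all__ = ["BoxCoxSpec", "transform", "inverse_transform", "boxcox_search"]

IDENTITY_LAMBDA = 1.0


@dataclass
class BoxCoxSpec:
    """A fitted response transform: y -> ((y + shift)**lam - 1) / lam.

    ``lam = 0`` is the natural-log limit.  ``objective_value`` is the R2CV
    attained by the selected PLS model on the transformed response;
    ``fallback`` marks the case where every candidate model failed and the
    identity was returned by default.
    """

    lam: float = IDENTITY_LAMBDA
    shift: float = 0.0
    objective_value: float = float("nan")
    k: int = 1
    fallback: bool = False

    @property
    def is_identity(self) -> bool:
        return self.lam == IDENTITY_LAMBDA and self.shift == 0.0


def transform(y, lam: float, shift: float = 0.0) -> np.ndarray:
    """Apply the power transform; lam = 0 gives log(y + shift)."""
    y = np.asarray(y, dtype=float)
    shifted = y + shift
    if np.any(shifted <= 0):
        raise ValueError("Box-Cox requires strictly positive (shifted) values")
    return _boxcox(shifted, lam)


def inverse_transform(z, lam: float, shift: float = 0.0) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    return _inv_boxcox(z, lam) - shift


def default_shift(y) -> float:
    """Zero unless the data contain non-positive values."""
    y = np.asarray(y, dtype=float)
    m = float(y.min())
    if m > 0:
        return 0.0
    return abs(m) + 1e-6 * max(1.0, float(np.ptp(y)))


def _score_lambda(X, y, lam, shift, k_max, tau):
    try:
        z = transform(y, lam, shift)
        if not np.all(np.isfinite(z)) or float(np.std(z, ddof=1)) <= 0:
            return None
        curves = loo_cv(X, z, k_max)
        k = select_k(curves.rmsecv, tau=tau)
        r2cv = float(curves.r2cv[k - 1])
        if not np.isfinite(r2cv):
            return None
        return r2cv, k
    except (ValueError, FloatingPointError):
        return None


def boxcox_search(
    X,
    y,
    k_max: int,
    tau: float = 0.02,
    grid=None,
    min_gain: float = 0.01,
    method: str = "grid",
    seed: int | None = None,
    ga_population: int = 30,
    ga_generations: int = 50,
) -> BoxCoxSpec:
    """Search for the transform exponent maximizing R2CV.

    Parameters
    ----------
    X : design matrix (array or DesignMatrix)
    y : response on its original scale (shift applied internally if needed)
    k_max : maximum latent variables considered per candidate
    tau : RMSECV slope threshold handed to :func:`select_k`
    grid : candidate exponents (default -2.0 .. 3.0 step 0.1)
    min_gain : identity is kept unless a candidate improves R2CV by more
    method : "grid" (reference) or "ga"
    """
    y = np.asarray(y, dtype=float).ravel()
    shift = default_shift(y)
    if grid is None:
        grid = np.round(np.arange(-2.0, 3.0 + 1e-9, 0.1), 10)

    identity = _score_lambda(X, y, IDENTITY_LAMBDA, shift, k_max, tau)

    if method == "ga":
        candidates = _ga_candidates(
            X, y, shift, k_max, tau, seed=seed,
            population=ga_population, generations=ga_generations,
        )
    else:
        candidates = [(float(lam),) + s for lam in grid if (s := _score_lambda(X, y, lam, shift, k_max, tau))]

    if not candidates and identity is None:
        return BoxCoxSpec(lam=IDENTITY_LAMBDA, shift=shift, fallback=True, objective_value=float("nan"))

    best = max(candidates, key=lambda c: c[1]) if candidates else None
    if identity is not None:
        id_r2cv, id_k = identity
        if best is None or best[1] <= id_r2cv + min_gain:
            return BoxCoxSpec(lam=IDENTITY_LAMBDA, shift=shift, objective_value=id_r2cv, k=id_k)
    if best is None:
        return BoxCoxSpec(lam=IDENTITY_LAMBDA, shift=shift, fallback=True, objective_value=float("nan"))
    lam, r2cv, k = best
    return BoxCoxSpec(lam=lam, shift=shift, objective_value=r2cv, k=k)


def _ga_candidates(X, y, shift, k_max, tau, seed, population, generations,
                   lo: float = -2.0, hi: float = 3.0):
    """Tournament-selection GA over the exponent; returns scored candidates."""
    rng = np.random.default_rng(seed)
    pop = rng.uniform(lo, hi, size=population)
    scored: dict[float, tuple] = {}

    def fitness(lam):
        lam = float(np.clip(lam, lo, hi))
        key = round(lam, 6)
        if key not in scored:
            s = _score_lambda(X, y, lam, shift, k_max, tau)
            scored[key] = (lam,) + s if s else None
        entry = scored[key]
        return entry[1] if entry else -np.inf

    fit = np.array([fitness(l) for l in pop])
    for _ in range(generations):
        new = []
        for _ in range(population):
            i, j = rng.integers(0, population, 2)
            parent_a = pop[i] if fit[i] >= fit[j] else pop[j]
            i, j = rng.integers(0, population, 2)
            parent_b = pop[i] if fit[i] >= fit[j] else pop[j]
            w = rng.uniform()
            child = w * parent_a + (1 - w) * parent_b
            if rng.uniform() < 0.2:
                child += rng.normal(0, 0.2)
            new.append(float(np.clip(child, lo, hi)))
        pop = np.array(new)
        fit = np.array([fitness(l) for l in pop])
    return [c for c in scored.values() if c is not None]
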