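"""Resampling-based significance for fitted PLS factorial models.

Coefficient tests use Wu's delete-one jackknife ("full cross validation"):
the whole fixed-structure pipeline (frozen component count and response
transform) is refit with each observation removed, and the weighted
jackknife variance feeds a two-sided t-test.  Confidence intervals for
coefficients and for every factor-cell prediction come from the wild
bootstrap with HC3 residual rescaling.  Cell CIs drive compact letter
displays where two cells share a letter exactly when their intervals
intersect, "A" marking the largest prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .boxcox import BoxCoxSpec, inverse_transform
from .dof import leverage, pls_dof
from .plsreg import fit_pls

__all__ = [
    "JackknifeReport",
    "WildBootstrapReport",
    "LetterDisplay",
    "wu_jackknife",
    "wild_bootstrap",
    "compare_cells",
    "letter_display",
]


def _raw_coefs(X, z, k):
    """Raw-scale (intercept, coefficients) of the fixed-k pipeline fit."""
    fit = fit_pls(X, z, k)
    return fit.intercept_raw, fit.coef_raw, fit


@dataclass
class JackknifeReport:
    """Per-coefficient Wu-jackknife variances, t statistics and p-values."""

    columns: list[str]
    coef: np.ndarray
    variance: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: float
    method: str = "Wu full cross validation"
    weighted: bool = True
    degenerate: np.ndarray = None


def wu_jackknife(X, z, k: int, weighted: bool = True, dof: float | None = None) -> JackknifeReport:
    """Wu's jackknife coefficient tests on the fixed-structure pipeline.

    Every observation is deleted in turn and the full pipeline
    (centering/scaling and the PLS fit at frozen ``k``) is re-estimated.
    With ``weighted=True`` (default) the variance is Wu's leverage-weighted
    form ``sum_i (1 - h_i) (b_(i) - b)^2``; otherwise the classic
    delete-one jackknife.  t statistics are referenced to Student-t with
    ``n - dof`` degrees of freedom (``dof`` from the model's effective
    degrees of freedom unless supplied).
    """
    Xarr = np.asarray(getattr(X, "X", X), dtype=float)
    columns = list(getattr(X, "columns", [f"x{j}" for j in range(Xarr.shape[1])]))
    z = np.asarray(z, dtype=float).ravel()
    n, p = Xarr.shape
    if n <= p + 1:
        raise ValueError("Wu jackknife needs n > number of coefficients + 1")
    intercept, beta, fit = _raw_coefs(Xarr, z, k)
    h = leverage(Xarr, z, k)
    if dof is None:
        dof = pls_dof(Xarr, z, k)

    deleted = np.zeros((n, p))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        _, bi, _ = _raw_coefs(Xarr[mask], z[mask], k)
        deleted[i] = bi
        mask[i] = True

    dev = deleted - beta
    if weighted:
        variance = ((1.0 - h)[:, None] * dev**2).sum(axis=0)
    else:
        mean_del = deleted.mean(axis=0)
        variance = (n - 1) / n * ((deleted - mean_del) ** 2).sum(axis=0)
    variance = np.maximum(variance, 0.0)

    # zero residual variance (exact fit) leaves only rounding noise in the
    # delete-one coefficients: flag as degenerate rather than testing
    resid_scale = float((fit.residuals**2).sum())
    z_scale = float(((z - z.mean()) ** 2).sum()) or 1.0
    exact_fit = resid_scale <= 1e-20 * z_scale
    degenerate = (variance <= 0) | (exact_fit & (variance <= 1e-16 * np.maximum(beta**2, 1.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.inf * np.sign(beta), beta / np.sqrt(variance))
    df_t = max(n - dof, 1.0)
    pvals = np.where(degenerate, 0.0, 2.0 * stats.t.sf(np.abs(t), df_t))
    return JackknifeReport(
        columns=columns,
        coef=beta,
        variance=variance,
        t=t,
        p=pvals,
        df=df_t,
        weighted=weighted,
        degenerate=degenerate,
    )


@dataclass
class CellEstimate:
    """Prediction for one factor-level combination, with its 95% CI.

    Values live on the model (transformed) scale; ``*_back`` are mapped
    back to the original response units when a transform is attached.
    """

    cell: tuple
    pred: float
    lower: float
    upper: float
    pred_back: float = float("nan")
    lower_back: float = float("nan")
    upper_back: float = float("nan")


@dataclass
class WildBootstrapReport:
    """Percentile CIs from wild-bootstrap (HC3) refits of the pipeline."""

    columns: list[str]
    coef: np.ndarray
    coef_lower: np.ndarray
    coef_upper: np.ndarray
    cells: dict = field(default_factory=dict)  # cell id -> CellEstimate
    n_resamples: int = 2000
    seed: int = 0
    alpha: float = 0.05
    aux: str = "rademacher"

    def coef_significant(self) -> np.ndarray:
        """CI excludes zero."""
        return (self.coef_lower > 0) | (self.coef_upper < 0)


def wild_bootstrap(
    X,
    z,
    k: int,
    cells: dict | None = None,
    n_resamples: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    transform: BoxCoxSpec | None = None,
    aux: str = "rademacher",
) -> WildBootstrapReport:
    """Wild bootstrap with HC3 rescaling on the fixed-structure pipeline.

    Residuals of the full fit are scaled by ``1/(1 - h_i)`` (leverage from
    the linearized PLS hat operator; values at 1 are capped with a
    warning), multiplied by auxiliary random signs and added back to the
    fitted values; the pipeline is refit on every pseudo-response.
    Percentile 95% CIs are reported for each raw-scale coefficient and
    each factor-cell prediction.
    """
    Xarr = np.asarray(getattr(X, "X", X), dtype=float)
    columns = list(getattr(X, "columns", [f"x{j}" for j in range(Xarr.shape[1])]))
    z = np.asarray(z, dtype=float).ravel()
    n, p = Xarr.shape
    intercept, beta, fit = _raw_coefs(Xarr, z, k)
    h = leverage(Xarr, z, k)
    scaled_resid = fit.residuals / (1.0 - h)
    cells = cells or {}
    cell_ids = list(cells)
    cell_mat = np.array([cells[c] for c in cell_ids]) if cell_ids else np.zeros((0, p))

    rng = np.random.default_rng(seed)
    boot_coef = np.zeros((n_resamples, p))
    boot_cell = np.zeros((n_resamples, len(cell_ids)))
    for b in range(n_resamples):
        if aux == "rademacher":
            v = rng.choice((-1.0, 1.0), size=n)
        elif aux == "mammen":
            golden = (1 + np.sqrt(5)) / 2
            v = np.where(
                rng.uniform(size=n) < golden / np.sqrt(5), 1 - golden, golden
            )
        else:
            raise ValueError(f"unknown auxiliary distribution {aux!r}")
        zb = fit.fitted + v * scaled_resid
        ib, bb, _ = _raw_coefs(Xarr, zb, k)
        boot_coef[b] = bb
        if cell_ids:
            boot_cell[b] = ib + cell_mat @ bb

    qlo, qhi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    c_lo, c_hi = np.percentile(boot_coef, [qlo, qhi], axis=0)
    report = WildBootstrapReport(
        columns=columns,
        coef=beta,
        coef_lower=c_lo,
        coef_upper=c_hi,
        n_resamples=n_resamples,
        seed=seed,
        alpha=alpha,
        aux=aux,
    )
    if cell_ids:
        p_lo, p_hi = np.percentile(boot_cell, [qlo, qhi], axis=0)
        point = intercept + cell_mat @ beta
        for i, cid in enumerate(cell_ids):
            est = CellEstimate(cell=cid, pred=float(point[i]), lower=float(p_lo[i]), upper=float(p_hi[i]))
            if transform is not None:
                est.pred_back = float(inverse_transform(point[i], transform.lam, transform.shift))
                est.lower_back = float(inverse_transform(p_lo[i], transform.lam, transform.shift))
                est.upper_back = float(inverse_transform(p_hi[i], transform.lam, transform.shift))
            report.cells[cid] = est
    return report


def compare_cells(report: WildBootstrapReport, cell_a, cell_b) -> bool:
    """True iff the two cells' CIs are disjoint (touching counts as overlap)."""
    a = report.cells[cell_a]
    b = report.cells[cell_b]
    return a.lower > b.upper or b.lower > a.upper


@dataclass
class LetterDisplay:
    """Compact letter display over cells; "A" sits on the largest prediction."""

    letters: dict  # cell id -> display string, e.g. "AB"
    letter_sets: dict  # cell id -> frozenset of letter symbols ("AA" is one symbol)
    order: list  # cells sorted by descending prediction

    def share_letter(self, a, b) -> bool:
        return bool(self.letter_sets[a] & self.letter_sets[b])


def _letter_symbol(i: int) -> str:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if i < 26:
        return alphabet[i]
    return alphabet[i // 26 - 1] + alphabet[i % 26]


def letter_display(report: WildBootstrapReport) -> LetterDisplay:
    """Insert-and-absorb letters over the CI-overlap relation.

    Two cells share a letter iff their confidence intervals intersect;
    letters are ranked so the largest predicted value (model scale)
    carries "A".
    """
    cell_ids = list(report.cells)
    if not cell_ids:
        raise ValueError("report has no cells")
    classes: list[set] = [set(cell_ids)]
    for i, a in enumerate(cell_ids):
        for b in cell_ids[i + 1:]:
            if not compare_cells(report, a, b):
                continue  # not significantly different: may share
            new_classes = []
            for cls in classes:
                if a in cls and b in cls:
                    wo_a = cls - {a}
                    wo_b = cls - {b}
                    new_classes.extend(c for c in (wo_a, wo_b) if c)
                else:
                    new_classes.append(cls)
            # absorb classes contained in another
            classes = [
                c
                for idx, c in enumerate(new_classes)
                if not any(c < d or (c == d and idx2 < idx) for idx2, d in enumerate(new_classes))
            ]

    pred = {c: report.cells[c].pred for c in cell_ids}
    classes.sort(key=lambda cls: (-max(pred[c] for c in cls), -min(pred[c] for c in cls)))
    symbols = {id(cls): _letter_symbol(i) for i, cls in enumerate(classes)}
    order = sorted(cell_ids, key=lambda c: -pred[c])
    letter_sets = {
        c: frozenset(symbols[id(cls)] for cls in classes if c in cls) for c in cell_ids
    }
    letters = {
        c: "".join(symbols[id(cls)] for cls in classes if c in cls) for c in cell_ids
    }
    disp = LetterDisplay(letters=letters, letter_sets=letter_sets, order=order)
    _assert_sound(report, disp)
    return disp


def _assert_sound(report: WildBootstrapReport, disp: LetterDisplay) -> None:
    """Post-hoc check: shares-a-letter <=> CIs intersect, every cell lettered."""
    ids = list(report.cells)
    for c in ids:
        if not disp.letters[c]:
            raise AssertionError(f"cell {c} received no letter")
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            different = compare_cells(report, a, b)
            share = disp.share_letter(a, b)
            if different and share:
                raise AssertionError(f"cells {a} and {b} differ but share a letter")
            if not different and not share:
                raise AssertionError(f"cells {a} and {b} overlap but share no letter")
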