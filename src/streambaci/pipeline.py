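"""End-to-end analysis over attributes and factorial designs.

For each attribute the pipeline runs (a) the KS2 and BCa-overlap group
panels, (b) the Box-Cox/PLS factorial model with leave-one-out selection,
and (c) Wu-jackknife and wild-bootstrap significance with compact letter
displays, then renders the three-panel report tables.  Models whose R2CV
falls at or below the suppression floor are reported as "--" in the letters
panel; diagnostics (residual normality, variance homogeneity) are always
recorded and never gate the analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .boxcox import boxcox_search, transform
from .design import build_design, cell_rows
from .dof import pls_dof
from .inference import compare_cells, letter_display, wild_bootstrap, wu_jackknife
from .nonparam import group_panels
from .plsreg import fit_pls, loo_cv, select_k
from .tables import read_observations, site_year_means, validate_observations

__all__ = [
    "AnalysisConfig",
    "InferenceReport",
    "run_analysis",
    "pearson_screen",
    "render_tables",
    "format_p",
]

DESIGNS = ("treatment-group", "watershed", "downstream")

GROUP_ORDER = ["clearcut variable", "clearcut uniform", "thinned", "reference"]
DOWNSTREAM_ORDER = ["downstream harvest", "downstream reference"]


@dataclass
class AnalysisConfig:
    """Knobs for one full analysis run."""

    input_path: str | None = None
    design: str = "treatment-group"
    attributes: list | None = None
    alpha: float = 0.05
    n_boot_bca: int = 10_000
    n_boot_wild: int = 2000
    select_k_tau: float = 0.02
    boxcox_grid: list | None = None
    boxcox_method: str = "grid"
    boxcox_min_gain: float = 0.01
    r2cv_floor: float = 0.0
    pooling: str = "site-year"
    jackknife_weighted: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")


@dataclass
class ModelSummary:
    attribute: str
    lam: float
    shift: float
    k: int
    r2: float
    r2cv: float
    rmsecv_curve: list
    dof: float
    shapiro_p: float
    levene_factor_p: float
    levene_period_p: float
    suppressed: bool
    n: int


@dataclass
class InferenceReport:
    """Per-attribute panels plus model diagnostics for one design."""

    design: str
    panel_a: pd.DataFrame | None  # KS2 p-values (group designs only)
    panel_b: pd.DataFrame | None  # BCa comparison codes
    panel_c: pd.DataFrame  # letters "pre/post" (or "--") per unit x attribute
    models: list = field(default_factory=list)  # ModelSummary
    letters: dict = field(default_factory=dict)  # attribute -> LetterDisplay
    wild_reports: dict = field(default_factory=dict)  # attribute -> WildBootstrapReport
    jackknife: dict = field(default_factory=dict)
    run_log: list = field(default_factory=list)
    seed: int = 0


def _design_rows(table: pd.DataFrame, design: str, pooling: str) -> pd.DataFrame:
    df = site_year_means(table) if pooling == "site-year" else table
    is_downstream = df["group"].str.contains("downstream", case=False)
    if design == "downstream":
        return df[is_downstream].copy()
    return df[~is_downstream].copy()


def _factor_levels(df: pd.DataFrame, design: str):
    if design == "watershed":
        name = "watershed"
        values = df["site"].to_numpy(dtype=object)
        order = list(dict.fromkeys(df["site"]))
    else:
        name = "treatment"
        values = df["group"].to_numpy(dtype=object)
        present = list(dict.fromkeys(df["group"]))
        canonical = GROUP_ORDER if design == "treatment-group" else DOWNSTREAM_ORDER
        order = [g for g in canonical if g in present] + [g for g in present if g not in canonical]
    return name, values, order


def run_analysis(config: AnalysisConfig, table: pd.DataFrame | None = None) -> InferenceReport:
    """Run the full multi-method analysis for one design.

    ``table`` may be passed directly; otherwise ``config.input_path`` is
    read.  Outputs are written under ``config.output_dir`` when set.
    """
    if table is None:
        if config.input_path is None:
            raise ValueError("either a table or config.input_path is required")
        table = read_observations(config.input_path)
    else:
        validate_observations(table)

    df = _design_rows(table, config.design, config.pooling)
    if df.empty:
        raise ValueError(f"no rows for design {config.design!r}")
    attributes = config.attributes or list(df["attribute"].unique())

    master = np.random.SeedSequence(config.seed)
    log: list[dict] = []
    report = InferenceReport(design=config.design, panel_a=None, panel_b=None,
                             panel_c=pd.DataFrame(), seed=config.seed)

    # panels A and B: group-level KS2 and BCa codes (not for watershed design)
    if config.design in ("treatment-group", "downstream"):
        sub = table[table["attribute"].isin(attributes)]
        sub = sub[sub["group"].str.contains("downstream", case=False) == (config.design == "downstream")]
        panel_seed = int(master.spawn(1)[0].generate_state(1)[0] % (2**31))
        panels = group_panels(
            sub, attributes=attributes, alpha=config.alpha,
            n_boot=config.n_boot_bca, seed=panel_seed, pooling=config.pooling,
        )
        report.panel_a = panels.pivot(index="group", columns="attribute", values="ks_p")
        report.panel_b = panels.pivot(index="group", columns="attribute", values="code")
        report.panel_b_detail = panels
        log.append({"event": "group_panels", "seed": panel_seed})

    letter_rows: dict[tuple, dict] = {}
    for attr in attributes:
        sub = df[df["attribute"] == attr]
        if sub.empty:
            log.append({"event": "skip_attribute", "attribute": attr, "reason": "absent"})
            continue
        fname, fvalues, forder = _factor_levels(sub, config.design)
        dm = build_design(
            [(fname, fvalues, forder), ("period", sub["period"].to_numpy(dtype=object), ["pre", "post"])],
            with_interactions=True,
        )
        y = sub["value"].to_numpy(dtype=float)
        k_max = dm.n_cols
        attr_seed = int(master.spawn(1)[0].generate_state(1)[0] % (2**31))
        try:
            spec = boxcox_search(
                dm, y, k_max=k_max, tau=config.select_k_tau,
                grid=config.boxcox_grid, min_gain=config.boxcox_min_gain,
                method=config.boxcox_method, seed=attr_seed,
            )
            z = transform(y, spec.lam, spec.shift)
            curves = loo_cv(dm, z, k_max)
            k = select_k(curves.rmsecv, tau=config.select_k_tau)
            fit = fit_pls(dm, z, k)
            dof = pls_dof(dm, z, k)
            r2cv = float(curves.r2cv[k - 1])
        except ValueError as err:
            log.append({"event": "model_failure", "attribute": attr, "error": str(err)})
            for unit in forder:
                letter_rows.setdefault((unit,), {})[attr] = "--"
            continue

        suppressed = (not np.isfinite(r2cv)) or r2cv <= config.r2cv_floor

        shapiro_p = float(stats.shapiro(fit.residuals).pvalue) if 3 <= len(y) <= 5000 else float("nan")
        lev_f = _levene_by(fit.residuals, fvalues)
        lev_p = _levene_by(fit.residuals, sub["period"].to_numpy(dtype=object))

        report.models.append(
            ModelSummary(
                attribute=attr, lam=spec.lam, shift=spec.shift, k=k,
                r2=fit.r2, r2cv=r2cv, rmsecv_curve=[float(v) for v in curves.rmsecv],
                dof=dof, shapiro_p=shapiro_p, levene_factor_p=lev_f,
                levene_period_p=lev_p, suppressed=bool(suppressed), n=len(y),
            )
        )
        log.append(
            {
                "event": "model", "attribute": attr, "lambda": spec.lam,
                "shift": spec.shift, "k": k, "r2cv": r2cv,
                "suppressed": bool(suppressed), "seed": attr_seed,
            }
        )

        if suppressed:
            for unit in forder:
                letter_rows.setdefault((unit,), {})[attr] = "--"
            continue

        jk = wu_jackknife(dm, z, k, weighted=config.jackknife_weighted, dof=dof)
        report.jackknife[attr] = jk
        wb_seed = int(master.spawn(1)[0].generate_state(1)[0] % (2**31))
        wb = wild_bootstrap(
            dm, z, k, cells=cell_rows(dm), n_resamples=config.n_boot_wild,
            seed=wb_seed, alpha=config.alpha, transform=spec,
        )
        report.wild_reports[attr] = wb
        disp = letter_display(wb)
        report.letters[attr] = disp
        log.append({"event": "wild_bootstrap", "attribute": attr, "seed": wb_seed})

        for unit in forder:
            pre_cell, post_cell = (unit, "pre"), (unit, "post")
            if pre_cell not in wb.cells or post_cell not in wb.cells:
                continue
            sig = compare_cells(wb, pre_cell, post_cell)
            entry = f"{disp.letters[pre_cell]}/{disp.letters[post_cell]}" + ("*" if sig else "")
            letter_rows.setdefault((unit,), {})[attr] = entry

    report.panel_c = pd.DataFrame(
        [dict(unit=unit[0], **vals) for unit, vals in letter_rows.items()]
    ).set_index("unit") if letter_rows else pd.DataFrame()
    report.run_log = log

    if config.output_dir:
        render_tables(report, config.output_dir)
    return report


def _levene_by(resid: np.ndarray, labels) -> float:
    groups = [resid[np.asarray(labels) == lv] for lv in pd.unique(np.asarray(labels, dtype=object))]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        return float("nan")
    return float(stats.levene(*groups, center="median").pvalue)


@dataclass
class CorrelationResult:
    pair: tuple
    stratum: tuple  # (harvested/reference, period)
    r: float
    r2: float
    p: float
    n: int
    significant: bool
    flagged: bool = False


def pearson_screen(table: pd.DataFrame, pairs, strata=None) -> list[CorrelationResult]:
    """Pearson correlations between attribute pairs on site-year averages.

    Stratified by harvested-vs-reference x pre/post by default.  R2 is
    reported as significant only when p <= 0.05; a constant series yields
    a flagged, undefined correlation.
    """
    df = site_year_means(table)
    wide = df.pivot_table(index=["site", "group", "period", "year"], columns="attribute",
                          values="value").reset_index()
    harvested = ~wide["group"].str.contains("reference", case=False)
    wide["stratum_class"] = np.where(harvested, "harvested", "reference")
    if strata is None:
        strata = [(c, p) for c in ("harvested", "reference") for p in ("pre", "post")]

    out = []
    for a, b in pairs:
        for cls, period in strata:
            sub = wide[(wide["stratum_class"] == cls) & (wide["period"] == period)]
            sub = sub.dropna(subset=[a, b]) if a in sub.columns and b in sub.columns else sub.iloc[0:0]
            n = len(sub)
            if n < 3:
                out.append(CorrelationResult((a, b), (cls, period), float("nan"), float("nan"),
                                             float("nan"), n, False, flagged=True))
                continue
            x = sub[a].to_numpy(dtype=float)
            yv = sub[b].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(yv) == 0:
                out.append(CorrelationResult((a, b), (cls, period), float("nan"), float("nan"),
                                             float("nan"), n, False, flagged=True))
                continue
            r, p = stats.pearsonr(x, yv)
            out.append(CorrelationResult((a, b), (cls, period), float(r), float(r) ** 2,
                                         float(p), n, bool(p <= 0.05)))
    return out


def format_p(p: float, alpha: float = 0.05) -> str:
    """Two-decimal p-value, round half up, asterisk when significant."""
    if not np.isfinite(p):
        return "--"
    text = str(Decimal(repr(float(p))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return text + ("*" if p <= alpha else "")


def render_tables(report: InferenceReport, output_dir) -> dict:
    """Write the three-panel tables and model details as CSV files."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    if report.panel_a is not None:
        pa = report.panel_a.map(format_p)
        pa.to_csv(outdir / "panel_a_ks2.csv")
        written["panel_a"] = outdir / "panel_a_ks2.csv"
    if report.panel_b is not None:
        report.panel_b.to_csv(outdir / "panel_b_bca.csv")
        written["panel_b"] = outdir / "panel_b_bca.csv"
    if not report.panel_c.empty:
        report.panel_c.to_csv(outdir / "panel_c_letters.csv")
        written["panel_c"] = outdir / "panel_c_letters.csv"

    if report.models:
        details = pd.DataFrame(
            {
                "attribute": m.attribute,
                "exponent": m.lam,
                "shift": m.shift,
                "k": m.k,
                "R2": m.r2,
                "R2CV": m.r2cv,
                "DoF": m.dof,
                "n": m.n,
                "shapiro_p": m.shapiro_p,
                "levene_factor_p": m.levene_factor_p,
                "levene_period_p": m.levene_period_p,
                "suppressed": m.suppressed,
                "rmsecv_curve": ";".join(f"{v:.6g}" for v in m.rmsecv_curve),
            }
            for m in report.models
        )
        details.to_csv(outdir / "model_details.csv", index=False)
        written["model_details"] = outdir / "model_details.csv"

    with open(outdir / "run_log.jsonl", "w") as fh:
        for entry in report.run_log:
            fh.write(json.dumps(entry) + "\n")
    written["run_log"] = outdir / "run_log.jsonl"
    return written
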