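"""Dummy-coded factorial design matrices.

Categorical factors are expanded into 0/1 indicator columns with the last
level of each factor deleted, so the columns of a crossed design stay
linearly independent.  Interaction columns are element-wise products of the
retained main-effect columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = ["DesignMatrix", "build_design", "cell_rows"]


@dataclass
class DesignMatrix:
    """A dummy-coded regressor array with labeled columns.

    Attributes
    ----------
    X : ndarray of shape (n_obs, n_cols)
        0/1 indicators (before any centering).
    columns : list of str
        Column labels, main effects first (in factor order) then
        pairwise interactions.
    factor_map : dict
        column label -> ("main", factor, level) or
        ("interaction", (factor_a, level_a), (factor_b, level_b)).
    levels : dict
        factor name -> ordered list of levels (last level is the one
        deleted from the coding).
    factor_values : dict
        factor name -> per-observation level array.
    """

    X: np.ndarray
    columns: list[str]
    factor_map: dict = field(default_factory=dict)
    levels: dict = field(default_factory=dict)
    factor_values: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]


def _ordered_levels(values: Sequence, explicit) -> list:
    if explicit is not None:
        extra = set(values) - set(explicit)
        if extra:
            raise ValueError(f"observed levels not in declared order: {sorted(map(str, extra))}")
        return list(explicit)
    seen: list = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen


def build_design(factors, with_interactions: bool = True) -> DesignMatrix:
    """Build a dummy-coded design matrix from categorical factors.

    Parameters
    ----------
    factors : list of (name, values) or (name, values, levels)
        ``values`` holds one level per observation; ``levels`` optionally
        fixes the level order (the last level is deleted).
    with_interactions : bool
        If True, append products of retained main-effect columns for
        every pair of factors, in factor-pair order.

    Returns
    -------
    DesignMatrix

    Raises
    ------
    ValueError
        If no indicator columns result (e.g. every factor has one level).
    """
    if not factors:
        raise ValueError("at least one factor is required")
    parsed = []
    n = None
    for spec in factors:
        if len(spec) == 2:
            name, values = spec
            lv = None
        else:
            name, values, lv = spec
        values = np.asarray(values, dtype=object)
        if n is None:
            n = len(values)
        elif len(values) != n:
            raise ValueError(f"factor {name!r} has {len(values)} values, expected {n}")
        parsed.append((name, values, _ordered_levels(values, lv)))

    columns: list[str] = []
    factor_map: dict = {}
    blocks: list[np.ndarray] = []
    main_cols: dict[str, list[tuple[str, object, np.ndarray]]] = {}

    for name, values, lv in parsed:
        cols_here = []
        for level in lv[:-1]:  # last level deleted
            col = (values == level).astype(float)
            label = f"{name}[{level}]"
            columns.append(label)
            factor_map[label] = ("main", name, level)
            blocks.append(col)
            cols_here.append((label, level, col))
        main_cols[name] = cols_here

    if with_interactions:
        names = [name for name, _, _ in parsed]
        for a, b in combinations(names, 2):
            for label_a, level_a, col_a in main_cols[a]:
                for label_b, level_b, col_b in main_cols[b]:
                    label = f"{label_a}:{label_b}"
                    columns.append(label)
                    factor_map[label] = ("interaction", (a, level_a), (b, level_b))
                    blocks.append(col_a * col_b)

    if not blocks:
        raise ValueError("design has zero columns (all factors single-level)")

    X = np.column_stack(blocks)
    return DesignMatrix(
        X=X,
        columns=columns,
        factor_map=factor_map,
        levels={name: lv for name, _, lv in parsed},
        factor_values={name: values for name, values, _ in parsed},
    )


def cell_rows(design: DesignMatrix) -> dict[tuple, np.ndarray]:
    """Dummy-coded regressor row for every factor-level combination present.

    Returns a mapping from the tuple of levels (in factor order) to the
    0/1 row vector that encodes that cell, for each combination observed
    in the design's factor values.
    """
    names = list(design.levels)
    n = design.n_obs
    observed = {tuple(design.factor_values[f][i] for f in names) for i in range(n)}

    cells: dict[tuple, np.ndarray] = {}
    for combo in sorted(observed, key=lambda c: [design.levels[f].index(l) for f, l in zip(names, c)]):
        row = np.zeros(design.n_cols)
        level_of = dict(zip(names, combo))
        for j, label in enumerate(design.columns):
            kind = design.factor_map[label]
            if kind[0] == "main":
                _, f, level = kind
                row[j] = 1.0 if level_of[f] == level else 0.0
            else:
                _, (fa, la), (fb, lb) = kind
                row[j] = 1.0 if (level_of[fa] == la and level_of[fb] == lb) else 0.0
        cells[combo] = row
    return cells
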