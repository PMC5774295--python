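"""Limiting-factor attribution: which variable most suppresses suitability.

At a cell, the limiting factor is the variable whose replacement by its
mean value at the presence localities most increases the predicted
suitability — i.e. the variable currently holding the prediction down the
most.  Cells where no substitution raises the prediction have no limiting
factor.  Attributions are aggregated into percentage shares per
range-change class, and simple late-minus-early difference maps show how
each factor itself changed between periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dynamics import CLASS_LABELS, ChangeMap, round_half_away
from .grids import ClimateStack, Grid, GridAlignmentError
from .maxent import MaxentModel, ProjectionError
from .occurrences import OccurrenceSet

__all__ = [
    "LimitingFactorMap",
    "FactorShares",
    "presence_variable_means",
    "limiting_factor_map",
    "factor_shares",
    "variable_change_map",
]

NO_FACTOR = -1  # no substitution increases the prediction


def presence_variable_means(stack: ClimateStack, occ: OccurrenceSet) -> dict[str, float]:
    """Mean of each stack variable at the presence localities."""
    vals = stack.values_at(occ.xy[:, 0], occ.xy[:, 1])
    return {n: float(vals[:, i].mean()) for i, n in enumerate(stack.names)}


@dataclass
class LimitingFactorMap:
    """Per-cell index of the limiting variable (NO_FACTOR where none)."""

    factor_index: np.ndarray  # int array; NO_FACTOR = none; masked cells NO_FACTOR
    mask: np.ndarray
    variable_names: list[str]
    reference_values: dict[str, float]
    grid: Grid

    def factor_mask(self, variable: str) -> np.ndarray:
        return self.factor_index == self.variable_names.index(variable)

    def legend(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"code": [NO_FACTOR] + list(range(len(self.variable_names))),
             "variable": ["none"] + self.variable_names}
        )


def limiting_factor_map(
    model: MaxentModel,
    stack: ClimateStack,
    presence_means: Mapping[str, float],
    clamp: bool = True,
) -> LimitingFactorMap:
    """Attribute every unmasked cell to its limiting variable.

    For each variable in turn the prediction is recomputed with that
    variable set to its presence-sample mean (others untouched, clamping as
    in projection); the factor is the variable with the largest positive
    gain, ties going to the first variable in model order.
    """
    names = model.features.var_names
    missing = [n for n in names if n not in stack.variables]
    if missing:
        raise ProjectionError(f"stack lacks model variable(s) {missing}")
    missing_means = [n for n in names if n not in presence_means]
    if missing_means:
        raise ValueError(f"presence_means lacks variable(s) {missing_means}")
    mask = stack.mask
    values = stack.values_matrix(names)
    base = model.predict_values(values, clamp=clamp)
    deltas = np.empty((values.shape[0], len(names)))
    for j, name in enumerate(names):
        swapped = values.copy()
        swapped[:, j] = presence_means[name]
        deltas[:, j] = model.predict_values(swapped, clamp=clamp) - base
    best = np.argmax(deltas, axis=1)  # first maximum = first variable in model order
    best_delta = deltas[np.arange(len(deltas)), best]
    flat = np.where(best_delta > 0, best, NO_FACTOR)
    factor = np.full(mask.shape, NO_FACTOR, dtype=int)
    factor[~mask] = flat
    return LimitingFactorMap(factor, mask.copy(), list(names), dict(presence_means), stack.template)


@dataclass
class FactorShares:
    """Percentage of a change class's cells attributed to each variable."""

    class_label: str
    n_cells: int
    shares: pd.DataFrame = field(default_factory=pd.DataFrame)  # variable, n_cells, share_pct
    undefined: bool = False  # empty class: shares are undefined, not zero

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.shares.assign(class_label=self.class_label).to_csv(path, index=False)


def factor_shares(lfmap: LimitingFactorMap, cmap: ChangeMap, class_label: str) -> FactorShares:
    """Shares (one decimal, half away from zero) within one change class.

    All variables are listed, plus a ``none`` row for cells without a
    limiting factor, so unrounded shares sum to exactly 100.  Rows are
    ordered by descending share, then variable name.
    """
    codes = {v: k for k, v in CLASS_LABELS.items()}
    if class_label not in codes:
        raise ValueError(f"unknown change class {class_label!r}")
    if lfmap.factor_index.shape != cmap.classes.shape:
        raise GridAlignmentError("limiting-factor and change maps are not aligned")
    in_class = cmap.class_mask(codes[class_label]) & ~lfmap.mask
    total = int(in_class.sum())
    if total == 0:
        return FactorShares(class_label, 0, pd.DataFrame(
            columns=["variable", "n_cells", "share_pct"]), undefined=True)
    idx = lfmap.factor_index[in_class]
    rows = []
    for j, name in enumerate([*lfmap.variable_names, "none"]):
        code = NO_FACTOR if name == "none" else j
        n = int((idx == code).sum())
        rows.append({"variable": name, "n_cells": n,
                     "share_pct": round_half_away(100.0 * n / total, 1)})
    df = pd.DataFrame(rows).sort_values(
        ["share_pct", "variable"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return FactorShares(class_label, total, df)


def variable_change_map(early: ClimateStack, late: ClimateStack, variable: str) -> Grid:
    """Late-minus-early difference map of one variable."""
    for stack in (early, late):
        if variable not in stack.variables:
            raise KeyError(f"variable {variable!r} missing from stack {stack.period_label!r}")
    a, b = early[variable], late[variable]
    if a.shape != b.shape or not a.transform.close_to(b.transform):
        raise GridAlignmentError("stacks are not aligned")
    mask = a.nodata_mask | b.nodata_mask
    vals = np.where(mask, np.nan, b.values - a.values)
    return a.like(vals, mask)
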