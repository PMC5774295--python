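"""Bioclimatic variable screening: correlation pruning and jackknife gains.

Highly collinear predictor sets overfit and transfer poorly to other
climate periods, so variables are screened in two steps: pairwise Pearson
correlation pruning at a threshold (default |r| > 0.85), with a
physiological-priority list deciding which member of a conflicting pair
survives, and a jackknife assessment that refits the model with each
variable alone and with each variable left out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import ClimateStack
from .maxent import (
    DEFAULT_CLASSES,
    DEFAULT_HINGE_KNOTS,
    build_features,
    evaluate_auc,
    fit_maxent,
)
from .occurrences import BackgroundSet, OccurrenceSet

__all__ = [
    "CorrelationReport",
    "JackknifeReport",
    "ConfigError",
    "correlation_matrix",
    "prune_correlated",
    "jackknife_contribution",
]


class ConfigError(ValueError):
    """Invalid screening configuration (e.g. unknown priority name)."""


@dataclass
class CorrelationReport:
    variable_names: list[str]
    r_matrix: np.ndarray
    n_cells_used: int
    degenerate: list[str] = field(default_factory=list)  # zero-variance variables

    def r(self, a: str, b: str) -> float:
        i, j = self.variable_names.index(a), self.variable_names.index(b)
        return float(self.r_matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r_matrix, index=self.variable_names, columns=self.variable_names)

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path)


def correlation_matrix(
    stack: ClimateStack, sample_mask: np.ndarray | None = None
) -> CorrelationReport:
    """Pearson correlations between variables over unmasked study cells.

    Zero-variance variables get NaN correlations (except the unit
    diagonal) and are flagged in ``degenerate``.
    """
    names = stack.names
    if len(names) < 2:
        raise ValueError("need at least two variables")
    keep = ~stack.mask
    if sample_mask is not None:
        keep &= np.asarray(sample_mask, dtype=bool)
    n = int(keep.sum())
    if n < 3:
        raise ValueError("need at least three cells to correlate")
    x = np.column_stack([stack[v].values[keep] for v in names])
    sd = x.std(axis=0)
    degenerate = [names[i] for i in np.flatnonzero(sd == 0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    for i in np.flatnonzero(sd == 0):
        r[i, :] = np.nan
        r[:, i] = np.nan
    np.fill_diagonal(r, 1.0)
    return CorrelationReport(list(names), r, n, degenerate)


def prune_correlated(
    report: CorrelationReport,
    threshold: float = 0.85,
    priority: list[str] | None = None,
) -> list[str]:
    """Drop variables until no retained pair has |r| > threshold.

    Within a conflicting pair the variable earlier in ``priority`` is kept;
    with no applicable priority, the one with the lower mean absolute
    correlation to all other retained variables is kept.  Pairs are handled
    most-correlated first; all ties break lexicographically, so the result
    is deterministic and, when the priority fully ranks the variables,
    independent of input ordering.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    priority = list(priority) if priority else []
    unknown = [p for p in priority if p not in report.variable_names]
    if unknown:
        raise ConfigError(f"priority names not among variables: {unknown}")
    rank = {name: i for i, name in enumerate(priority)}
    kept = sorted(report.variable_names)

    def mean_abs_r(name: str, pool: list[str]) -> float:
        vals = [abs(report.r(name, o)) for o in pool if o != name]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else 0.0

    while True:
        conflicts = []
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                r = report.r(a, b)
                if np.isfinite(r) and abs(r) > threshold:
                    conflicts.append((abs(r), a, b))
        if not conflicts:
            return [n for n in report.variable_names if n in kept]
        _, a, b = max(conflicts, key=lambda t: (t[0], tuple(reversed(t[1:]))))
        ra, rb = rank.get(a, np.inf), rank.get(b, np.inf)
        if ra != rb:
            drop = b if ra < rb else a
        else:
            ma, mb = mean_abs_r(a, kept), mean_abs_r(b, kept)
            if ma != mb:
                drop = a if ma > mb else b
            else:
                drop = max(a, b)  # lexicographically later
        kept.remove(drop)


@dataclass
class JackknifeReport:
    """Per-variable alone / leave-one-out gains and training AUCs."""

    table: pd.DataFrame  # columns: variable, gain_alone, gain_without, auc_alone, auc_without
    gain_all: float
    auc_all: float

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)


def jackknife_contribution(
    occ: OccurrenceSet,
    background: BackgroundSet,
    stack: ClimateStack,
    beta: float = 1.0,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    n_hinge_knots: int = DEFAULT_HINGE_KNOTS,
) -> JackknifeReport:
    """Refit with each variable alone and with all-but-that variable.

    Gains are regularized training gains (penalized log-likelihood
    improvement over the uniform model); AUCs are training AUCs of
    presences against the background.  A one-variable "without" set is
    empty and scores gain 0 / AUC 0.5 (the uniform model).
    """
    names = stack.names
    pres_vals = stack.values_at(occ.xy[:, 0], occ.xy[:, 1], names)
    bg_vals = stack.values_at(background.xy[:, 0], background.xy[:, 1], names)

    def run(sub: list[str]) -> tuple[float, float]:
        if not sub:
            return 0.0, 0.5
        cols = [names.index(s) for s in sub]
        p, b = pres_vals[:, cols], bg_vals[:, cols]
        both = np.vstack([p, b])
        bounds = {s: (float(both[:, i].min()), float(both[:, i].max())) for i, s in enumerate(sub)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fs, b_design = build_features(b, sub, classes, n_hinge_knots, bounds)
            model = fit_maxent(fs.transform(p), b_design, beta=beta, feature_set=fs)
        auc = evaluate_auc(model.eta(fs.transform(p)), model.eta(b_design))
        return model.gain, auc

    gain_all, auc_all = run(list(names))
    rows = []
    for v in names:
        gain_alone, auc_alone = run([v])
        gain_without, auc_without = run([n for n in names if n != v])
        rows.append(
            {"variable": v, "gain_alone": gain_alone, "gain_without": gain_without,
             "auc_alone": auc_alone, "auc_without": auc_without}
        )
    return JackknifeReport(pd.DataFrame(rows), gain_all, auc_all)
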