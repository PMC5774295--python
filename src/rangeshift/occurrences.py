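"""Occurrence handling: CSV ingestion, spatial thinning, sampling-bias surface.

Presence-only occurrence records are typically spatially clustered around
accessible places (roads, herbaria, towns).  Two standard mitigations are
implemented: distance-constrained thinning (keep the *maximum* number of
records that are pairwise at least ``min_dist`` apart) and a Gaussian
kernel-density bias surface used to draw background points with the same
spatial bias as the collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .grids import Grid

__all__ = [
    "OccurrenceSet",
    "BackgroundSet",
    "SchemaError",
    "SamplingError",
    "read_occurrences",
    "write_occurrences",
    "thin",
    "bias_surface",
    "sample_background",
]


class SchemaError(ValueError):
    """Occurrence CSV does not have the required columns / unique ids."""


class SamplingError(ValueError):
    """Requested more samples than there are cells with positive weight."""


@dataclass
class OccurrenceSet:
    """Presence localities in projected (metre) coordinates."""

    ids: list[str]
    xy: np.ndarray  # (n, 2) metres
    source_label: str = ""

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.ids = [str(i) for i in self.ids]
        if len(self.ids) != len(self.xy):
            raise ValueError("ids and coordinates differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise SchemaError("duplicate occurrence ids")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices) -> "OccurrenceSet":
        indices = list(indices)
        return OccurrenceSet(
            [self.ids[i] for i in indices], self.xy[indices], self.source_label
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "x": self.xy[:, 0], "y": self.xy[:, 1]})


@dataclass
class BackgroundSet:
    """Background (pseudo-absence) cells drawn from a bias surface."""

    xy: np.ndarray  # (n, 2) metres, cell centres
    weights_used: Grid | None = None
    seed: int = 0
    cells: np.ndarray = field(default=None)  # type: ignore[assignment]  # (n, 2) row/col

    def __len__(self) -> int:
        return len(self.xy)


def read_occurrences(path: str | Path, source_label: str | None = None) -> OccurrenceSet:
    """Read an ``id,x,y`` CSV of projected presence points."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"id", "x", "y"} - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s) {sorted(missing)} in {path}")
    try:
        x = df["x"].astype(float).to_numpy()
        y = df["y"].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric coordinate in {path}") from exc
    return OccurrenceSet(
        df["id"].astype(str).tolist(),
        np.column_stack([x, y]),
        source_label if source_label is not None else path.name,
    )


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    occ.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Thinning = exact maximum independent set on the <min_dist conflict graph.

_EXACT_COMPONENT_LIMIT = 25
_GREEDY_RESTARTS = 1000


def thin(occ: OccurrenceSet, min_dist_km: float) -> OccurrenceSet:
    """Maximum-cardinality subset with all pairwise distances >= ``min_dist_km``.

    Records closer than ``min_dist_km`` conflict; the retained subset is a
    maximum independent set of the conflict graph, solved exactly per
    connected component (branch and bound, include-first in sorted-id order,
    which makes tie-breaking deterministic and id-lexicographic).  Components
    larger than 25 records fall back to a seeded randomized greedy with 1000
    restarts, keeping the best subset found.
    """
    if min_dist_km <= 0:
        raise ValueError("min_dist must be positive")
    n = len(occ)
    if n == 0:
        return OccurrenceSet([], np.empty((0, 2)), occ.source_label)
    order = sorted(range(n), key=lambda i: occ.ids[i])
    xy = occ.xy[order]
    d = squareform(pdist(xy)) if n > 1 else np.zeros((1, 1))
    conflict = (d < min_dist_km * 1000.0) & ~np.eye(n, dtype=bool)

    # connected components of the conflict graph
    comp = -np.ones(n, dtype=int)
    n_comp = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = n_comp
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(conflict[u]):
                if comp[v] < 0:
                    comp[v] = n_comp
                    stack.append(int(v))
        n_comp += 1

    keep_sorted: list[int] = []
    for c in range(n_comp):
        nodes = np.flatnonzero(comp == c)
        if len(nodes) == 1:
            keep_sorted.append(int(nodes[0]))
            continue
        sub = conflict[np.ix_(nodes, nodes)]
        if len(nodes) <= _EXACT_COMPONENT_LIMIT:
            chosen = _mis_exact(sub)
        else:
            chosen = _mis_greedy(sub, restarts=_GREEDY_RESTARTS)
        keep_sorted.extend(int(nodes[i]) for i in chosen)

    keep_original = sorted(order[i] for i in keep_sorted)
    return occ.subset(keep_original)


def _mis_exact(adj: np.ndarray) -> list[int]:
    """Exact maximum independent set via bitset branch and bound.

    Nodes are explored in index order with the include-branch first and the
    incumbent replaced only on strict improvement, so among maximum subsets
    the one preferring the smallest indices (= lexicographically earliest
    ids) is returned.
    """
    k = adj.shape[0]
    nbr = [int(sum(1 << j for j in np.flatnonzero(adj[i]))) for i in range(k)]
    best = {"mask": 0, "count": -1}

    def rec(cand: int, chosen: int, count: int) -> None:
        if cand == 0:
            if count > best["count"]:
                best["count"] = count
                best["mask"] = chosen
            return
        if count + cand.bit_count() <= best["count"]:
            return
        v = (cand & -cand).bit_length() - 1
        bit = 1 << v
        rec(cand & ~(nbr[v] | bit), chosen | bit, count + 1)
        rec(cand & ~bit, chosen, count)

    rec((1 << k) - 1, 0, 0)
    return [i for i in range(k) if best["mask"] >> i & 1]


def _mis_greedy(adj: np.ndarray, restarts: int) -> list[int]:
    """Randomized greedy independent set, best of seeded restarts."""
    k = adj.shape[0]
    best: tuple[int, tuple[int, ...]] | None = None
    for r in range(restarts):
        rng = np.random.default_rng(r)
        perm = rng.permutation(k)
        taken: list[int] = []
        blocked = np.zeros(k, dtype=bool)
        for v in perm:
            if not blocked[v]:
                taken.append(int(v))
                blocked[adj[v]] = True
                blocked[v] = True
        cand = (-len(taken), tuple(sorted(taken)))
        if best is None or cand < best:
            best = cand
    assert best is not None
    return list(best[1])


# ---------------------------------------------------------------------------
# Sampling-bias surface and background draw.


def bias_surface(occ: OccurrenceSet, template: Grid, radius_km: float = 60.0) -> Grid:
    """Gaussian kernel density of the occurrences, rescaled to max 1.

    The search radius is taken as the kernel sigma, truncated at 3 sigma.
    With no occurrences the surface falls back to 1 on every unmasked cell
    (uniform background weighting).
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    sigma = radius_km * 1000.0
    out = np.zeros(template.shape, dtype=float)
    t = template.transform
    nr, nc = template.shape
    if len(occ) == 0:
        out[:] = 1.0
    else:
        reach = 3.0 * sigma
        xs = t.x_origin + (np.arange(nc) + 0.5) * t.dx
        ys = t.y_origin + (np.arange(nr) + 0.5) * t.dy
        for px, py in occ.xy:
            c0 = max(0, int(np.floor((px - reach - t.x_origin) / t.dx)))
            c1 = min(nc, int(np.ceil((px + reach - t.x_origin) / t.dx)) + 1)
            r0 = max(0, int(np.floor((py + reach - t.y_origin) / t.dy)))
            r1 = min(nr, int(np.ceil((py - reach - t.y_origin) / t.dy)) + 1)
            if c0 >= c1 or r0 >= r1:
                continue
            dx2 = (xs[c0:c1] - px) ** 2
            dy2 = (ys[r0:r1] - py) ** 2
            d2 = dy2[:, None] + dx2[None, :]
            kern = np.exp(-d2 / (2.0 * sigma**2))
            kern[d2 > reach**2] = 0.0
            out[r0:r1, c0:c1] += kern
        peak = out[~template.nodata_mask].max() if np.any(~template.nodata_mask) else 0.0
        if peak > 0:
            out /= peak
    out[template.nodata_mask] = np.nan
    return template.like(out)


def sample_background(
    bias: Grid,
    n: int,
    seed: int,
    exclude: OccurrenceSet | None = None,
) -> BackgroundSet:
    """Draw ``n`` distinct cells with probability proportional to the bias value."""
    if n < 1:
        raise ValueError("n must be >= 1")
    weights = np.where(bias.nodata_mask, 0.0, np.nan_to_num(bias.values, nan=0.0))
    weights = np.clip(weights, 0.0, None)
    if exclude is not None and len(exclude):
        row, col = bias.transform.cell_index(exclude.xy[:, 0], exclude.xy[:, 1])
        nr, nc = bias.shape
        ok = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
        weights[row[ok], col[ok]] = 0.0
    flat = weights.ravel()
    positive = np.flatnonzero(flat > 0)
    if len(positive) < n:
        raise SamplingError(
            f"requested {n} background cells but only {len(positive)} have positive weight"
        )
    p = flat[positive] / flat[positive].sum()
    rng = np.random.default_rng(seed)
    picked = positive[rng.choice(len(positive), size=n, replace=False, p=p)]
    rows, cols = np.unravel_index(picked, bias.shape)
    x, y = bias.transform.cell_center(rows, cols)
    return BackgroundSet(
        xy=np.column_stack([x, y]),
        weights_used=bias,
        seed=seed,
        cells=np.column_stack([rows, cols]),
    )
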