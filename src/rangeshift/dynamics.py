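"""Range dynamics: thresholding, change classification, centroid vectors.

A continuous suitability surface is cut to a presence/absence map with one
of two standard rules (maximum training sensitivity plus specificity, or
the 10th-percentile training presence score); pairs of binary maps are then
classified per cell into contraction / no change / expansion, with area
ratios expressed relative to the earlier period (contraction, no change)
or the later period (expansion).  Range movement is summarized both as the
single vector between range centroids and as a field of block-level
migration vectors (nearest earlier-period centroid for every later-period
block centroid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Grid, GridAlignmentError, area_of

__all__ = [
    "ABSENT", "CONTRACTION", "NO_CHANGE", "EXPANSION", "CLASS_LABELS",
    "Thresholds", "BinaryMap", "ChangeMap", "ChangeTable", "Vector", "VectorField",
    "CentroidError", "MatchingError",
    "mtss_threshold", "ten_percent_tp_threshold", "binarize",
    "change_map", "change_ratios", "change_table", "round_half_away",
    "overall_centroid", "centroid_vector", "block_centroids", "migration_vectors",
]

ABSENT, CONTRACTION, NO_CHANGE, EXPANSION = 0, 1, 2, 3
CLASS_LABELS = {ABSENT: "absent", CONTRACTION: "contraction",
                NO_CHANGE: "no_change", EXPANSION: "expansion"}


class CentroidError(ValueError):
    """Centroid of an empty range is undefined."""


class MatchingError(ValueError):
    """Vector matching needs a non-empty earlier-period centroid set."""


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 0.05 -> 0.1, -0.05 -> -0.1)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class Thresholds:
    mtss: float
    ten_percent_tp: float


def mtss_threshold(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Threshold maximizing sensitivity(presence >= t) + specificity(background < t).

    Candidates are the union of observed scores; ties resolve to the
    smallest maximizing threshold.
    """
    sp = np.sort(np.asarray(scores_presence, dtype=float))
    sb = np.sort(np.asarray(scores_background, dtype=float))
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    candidates = np.unique(np.concatenate([sp, sb]))
    # sensitivity: fraction of presences >= t ; specificity: background < t
    sens = 1.0 - np.searchsorted(sp, candidates, side="left") / sp.size
    spec = np.searchsorted(sb, candidates, side="left") / sb.size
    total = sens + spec
    return float(candidates[int(np.argmax(total))])  # argmax returns first (smallest t)


def ten_percent_tp_threshold(scores_presence: np.ndarray) -> float:
    """The (floor(0.1 m) + 1)-th order statistic of the presence scores."""
    sp = np.sort(np.asarray(scores_presence, dtype=float))
    if sp.size == 0:
        raise ValueError("need at least one presence score")
    return float(sp[int(np.floor(0.1 * sp.size))])


@dataclass
class BinaryMap:
    """Thresholded presence/absence map; masked cells are never suitable."""

    suitable: np.ndarray
    threshold_used: float
    period_label: str
    grid: Grid  # geometry carrier (transform, mask, cell area)

    def __post_init__(self) -> None:
        self.suitable = np.asarray(self.suitable, dtype=bool)
        if self.suitable.shape != self.grid.shape:
            raise ValueError("suitable array does not match grid shape")
        self.suitable = self.suitable & ~self.grid.nodata_mask

    @property
    def cell_area(self) -> float:
        return self.grid.cell_area

    @property
    def area_km2(self) -> float:
        return area_of(self.suitable, self.cell_area)


def binarize(prediction: Grid, threshold: float, period_label: str = "") -> BinaryMap:
    """suitable <=> unmasked and score >= threshold (boundary is suitable)."""
    with np.errstate(invalid="ignore"):
        suit = np.where(prediction.nodata_mask, False, prediction.values >= threshold)
    return BinaryMap(suit, threshold, period_label, prediction)


def _check_aligned(a: BinaryMap, b: BinaryMap) -> None:
    if a.suitable.shape != b.suitable.shape or not a.grid.transform.close_to(b.grid.transform):
        raise GridAlignmentError("binary maps are not aligned")


@dataclass
class ChangeMap:
    """Per-cell transition class between two periods."""

    classes: np.ndarray  # uint8 codes, see CLASS_LABELS
    pair_label: str
    grid: Grid

    def class_mask(self, code: int) -> np.ndarray:
        return self.classes == code

    @property
    def cell_area(self) -> float:
        return self.grid.cell_area


def change_map(early: BinaryMap, late: BinaryMap) -> ChangeMap:
    _check_aligned(early, late)
    classes = np.full(early.suitable.shape, ABSENT, dtype=np.uint8)
    classes[early.suitable & ~late.suitable] = CONTRACTION
    classes[early.suitable & late.suitable] = NO_CHANGE
    classes[~early.suitable & late.suitable] = EXPANSION
    label = f"{early.period_label}->{late.period_label}"
    return ChangeMap(classes, label, early.grid)


def change_ratios(
    contraction_km2: float,
    no_change_km2: float,
    expansion_km2: float,
    area_early: float | None = None,
    area_late: float | None = None,
) -> dict:
    """Ratio accounting on class areas (any consistent unit).

    The earlier-period area is contraction + no-change and the later-period
    area no-change + expansion (exact identities); explicit period areas may
    be passed instead when the class areas have been rounded independently
    of the period totals, as in published tables.  Contraction and
    no-change ratios are percentages of the earlier-period area, the
    expansion ratio a percentage of the later-period area, rounded to one
    decimal half away from zero.  Ratios with a zero denominator are None.
    """
    early = contraction_km2 + no_change_km2 if area_early is None else area_early
    late = no_change_km2 + expansion_km2 if area_late is None else area_late
    pct = lambda part, whole: (round_half_away(100.0 * part / whole, 1) if whole > 0 else None)
    return {
        "area_early": early,
        "area_late": late,
        "ratio_contraction": pct(contraction_km2, early),
        "ratio_no_change": pct(no_change_km2, early),
        "ratio_expansion": pct(expansion_km2, late),
    }


@dataclass
class ChangeTable:
    """Class areas (km^2) and the published-style percentage ratios."""

    pair_label: str
    areas: dict  # label -> km^2 for contraction / no_change / expansion
    area_early: float
    area_late: float
    ratio_contraction: float | None
    ratio_no_change: float | None
    ratio_expansion: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": self.pair_label,
                "class": ["contraction", "no_change", "expansion"],
                "area_km2": [self.areas[c] for c in ("contraction", "no_change", "expansion")],
                "ratio_pct": [self.ratio_contraction, self.ratio_no_change, self.ratio_expansion],
                "ratio_denominator": ["early", "early", "late"],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)


def change_table(cmap: ChangeMap) -> ChangeTable:
    areas = {
        label: area_of(cmap.class_mask(code), cmap.cell_area)
        for code, label in CLASS_LABELS.items()
        if code != ABSENT
    }
    r = change_ratios(areas["contraction"], areas["no_change"], areas["expansion"])
    return ChangeTable(
        pair_label=cmap.pair_label,
        areas=areas,
        area_early=r["area_early"],
        area_late=r["area_late"],
        ratio_contraction=r["ratio_contraction"],
        ratio_no_change=r["ratio_no_change"],
        ratio_expansion=r["ratio_expansion"],
    )


# ---------------------------------------------------------------------------
# Centroids and migration vectors


def overall_centroid(bmap: BinaryMap) -> tuple[float, float]:
    """Unweighted mean of suitable-cell centre coordinates (metres)."""
    rows, cols = np.nonzero(bmap.suitable)
    if rows.size == 0:
        raise CentroidError(f"range {bmap.period_label!r} is empty")
    x, y = bmap.grid.transform.cell_center(rows, cols)
    return float(x.mean()), float(y.mean())


def _bearing_deg(dx: float, dy: float) -> float:
    """Degrees clockwise from north of the displacement (dx east, dy north)."""
    return float(np.degrees(np.arctan2(dx, dy)) % 360.0)


@dataclass(frozen=True)
class Vector:
    source: tuple[float, float]
    target: tuple[float, float]
    distance_km: float
    bearing_deg: float

    @classmethod
    def between(cls, source, target) -> "Vector":
        dx = target[0] - source[0]
        dy = target[1] - source[1]
        return cls(tuple(source), tuple(target), float(np.hypot(dx, dy)) / 1000.0,
                   _bearing_deg(dx, dy))


@dataclass
class VectorField:
    vectors: list[Vector]
    pair_label: str = ""
    unmatched_sources: list[tuple[float, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.vectors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": self.pair_label,
                "source_x": [v.source[0] for v in self.vectors],
                "source_y": [v.source[1] for v in self.vectors],
                "target_x": [v.target[0] for v in self.vectors],
                "target_y": [v.target[1] for v in self.vectors],
                "distance_km": [v.distance_km for v in self.vectors],
                "bearing_deg": [v.bearing_deg for v in self.vectors],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)


def centroid_vector(early: BinaryMap, late: BinaryMap) -> VectorField:
    """Single vector from the earlier range centroid to the later one."""
    v = Vector.between(overall_centroid(early), overall_centroid(late))
    return VectorField([v], f"{early.period_label}->{late.period_label}")


def block_centroids(bmap: BinaryMap, block_km: float = 60.0) -> list[tuple[float, float]]:
    """Per-tile centroids of the suitable cells.

    The grid is partitioned into block_km x block_km tiles anchored at the
    raster origin (partial edge tiles allowed); each tile holding at least
    one suitable cell contributes the mean of its suitable-cell centres.
    Returned in row-major tile order, deterministic.
    """
    t = bmap.grid.transform
    if block_km * 1000.0 < t.dx:
        raise ValueError("block size must be at least one cell")
    rows, cols = np.nonzero(bmap.suitable)
    if rows.size == 0:
        return []
    x, y = t.cell_center(rows, cols)
    block_m = block_km * 1000.0
    bx = np.floor((x - t.x_origin) / block_m).astype(int)
    by = np.floor((t.y_origin - y) / block_m).astype(int)
    out: dict[tuple[int, int], list] = {}
    for i in range(rows.size):
        out.setdefault((by[i], bx[i]), []).append((x[i], y[i]))
    cents = []
    for key in sorted(out):
        pts = np.asarray(out[key])
        cents.append((float(pts[:, 0].mean()), float(pts[:, 1].mean())))
    return cents


def migration_vectors(
    centroids_early: list[tuple[float, float]],
    centroids_late: list[tuple[float, float]],
    pair_label: str = "",
) -> VectorField:
    """One vector per later-period centroid from its nearest earlier centroid.

    Ties on distance resolve to the lexicographically smallest earlier
    centroid.  Earlier centroids never chosen as a source (vanished range
    patches) are reported in ``unmatched_sources`` rather than vectorized.
    """
    if len(centroids_late) == 0:
        raise ValueError("no later-period centroids")
    if len(centroids_early) == 0:
        raise MatchingError("no earlier-period centroids to match against")
    early = np.asarray(centroids_early, dtype=float)
    order = np.lexsort((early[:, 1], early[:, 0]))  # lexicographic (x, y) tie-break
    early_sorted = early[order]
    vectors = []
    used: set[int] = set()
    for tx, ty in centroids_late:
        d = np.hypot(early_sorted[:, 0] - tx, early_sorted[:, 1] - ty)
        j = int(np.argmin(d))  # first minimum = lexicographically smallest source
        used.add(j)
        vectors.append(Vector.between((early_sorted[j, 0], early_sorted[j, 1]), (tx, ty)))
    unmatched = [
        (float(early_sorted[j, 0]), float(early_sorted[j, 1]))
        for j in range(len(early_sorted))
        if j not in used
    ]
    return VectorField(vectors, pair_label, unmatched)
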