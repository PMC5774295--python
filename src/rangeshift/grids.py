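"""Raster data model for projected, equal-area climate grids.

All analysis happens on grids that are already projected to a planar
equal-area / equidistant CRS, so a grid is just a 2-D array of values, a
north-up affine transform in metres and a nodata mask.  Row 0 is the
northernmost row; x grows east, y grows north; coordinates refer to cell
centres.  Two on-disk formats are supported: single-band float32 GeoTIFF
(georeferencing via the ModelPixelScale / ModelTiepoint tags) and the ESRI
ASCII grid text format.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import tifffile

__all__ = [
    "GridTransform",
    "Grid",
    "ClimateStack",
    "GridFormatError",
    "GridAlignmentError",
    "read_grid",
    "write_grid",
    "build_stack",
    "area_of",
]

# GeoTIFF tag codes used for single-band georeferenced rasters.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113
_ALIGN_TOL = 1e-6  # in units of one cell width


class GridFormatError(ValueError):
    """File could not be parsed in the requested raster format."""


class GridAlignmentError(ValueError):
    """Grids that must share geometry do not."""


@dataclass(frozen=True)
class GridTransform:
    """North-up affine transform: top-left corner and signed cell sizes.

    ``dx`` is positive (east), ``dy`` is negative (rows run north to
    south).  Units are metres.
    """

    x_origin: float
    y_origin: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy >= 0:
            raise ValueError("expected dx > 0 and dy < 0 (north-up grid)")

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int):
        x = self.x_origin + (np.asarray(col) + 0.5) * self.dx
        y = self.y_origin + (np.asarray(row) + 0.5) * self.dy
        return x, y

    def cell_index(self, x: np.ndarray | float, y: np.ndarray | float):
        col = np.floor((np.asarray(x) - self.x_origin) / self.dx).astype(int)
        row = np.floor((np.asarray(y) - self.y_origin) / self.dy).astype(int)
        return row, col

    def close_to(self, other: "GridTransform", tol_cells: float = _ALIGN_TOL) -> bool:
        tol = abs(self.dx) * tol_cells
        return (
            abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


@dataclass
class Grid:
    """One raster variable on a projected grid.

    ``values`` holds finite numbers wherever ``nodata_mask`` is False;
    masked cells may hold anything (conventionally NaN).
    """

    values: np.ndarray
    transform: GridTransform
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask shapes differ")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("non-finite values on unmasked cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area(self) -> float:
        """Cell area in km^2 (the grid is planar equal-area)."""
        return abs(self.transform.dx * self.transform.dy) / 1e6

    def cell_centers(self):
        """(X, Y) coordinate arrays of all cell centres, in metres."""
        rows, cols = np.indices(self.shape)
        return self.transform.cell_center(rows, cols)

    def values_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Sample values at projected points (nearest cell)."""
        row, col = self.transform.cell_index(np.asarray(x), np.asarray(y))
        nr, nc = self.shape
        if np.any((row < 0) | (row >= nr) | (col < 0) | (col >= nc)):
            raise ValueError("point outside grid extent")
        return self.values[row, col]

    def like(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        """New grid on the same geometry."""
        return Grid(
            values=values,
            transform=self.transform,
            nodata_mask=self.nodata_mask.copy() if mask is None else mask,
            crs_label=self.crs_label,
        )


@dataclass
class ClimateStack:
    """Named, geometrically aligned grids for one time period."""

    period_label: str
    variables: dict[str, Grid] = field(default_factory=dict)

    def __iter__(self) -> Iterator[str]:
        return iter(self.variables)

    def __getitem__(self, name: str) -> Grid:
        return self.variables[name]

    def __len__(self) -> int:
        return len(self.variables)

    @property
    def names(self) -> list[str]:
        return list(self.variables)

    @property
    def template(self) -> Grid:
        return next(iter(self.variables.values()))

    @property
    def mask(self) -> np.ndarray:
        """Unified nodata mask (union over member grids)."""
        m = np.zeros(self.template.shape, dtype=bool)
        for g in self.variables.values():
            m |= g.nodata_mask
        return m

    def values_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Cells x variables matrix over unmasked cells (row-major order)."""
        names = self.names if names is None else names
        keep = ~self.mask
        return np.column_stack([self.variables[n].values[keep] for n in names])

    def values_at(self, x: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        names = self.names if names is None else names
        return np.column_stack([self.variables[n].values_at(x, y) for n in names])

    def subset(self, names: list[str]) -> "ClimateStack":
        missing = [n for n in names if n not in self.variables]
        if missing:
            raise KeyError(f"variables not in stack: {missing}")
        return ClimateStack(self.period_label, {n: self.variables[n] for n in names})


def build_stack(grids: Mapping[str, Grid], period_label: str) -> ClimateStack:
    """Assemble aligned grids into a stack; nodata mask is the union.

    Raises :class:`GridAlignmentError` when shapes differ or transforms
    disagree by more than 1e-6 of a cell width.
    """
    if not grids:
        raise ValueError("need at least one grid")
    items = list(grids.items())
    ref = items[0][1]
    for name, g in items[1:]:
        if g.shape != ref.shape:
            raise GridAlignmentError(f"grid {name!r}: shape {g.shape} != {ref.shape}")
        if not g.transform.close_to(ref.transform):
            raise GridAlignmentError(f"grid {name!r}: transform mismatch")
    union = np.zeros(ref.shape, dtype=bool)
    for _, g in items:
        union |= g.nodata_mask
    out = {
        name: Grid(g.values.copy(), g.transform, union.copy(), g.crs_label)
        for name, g in items
    }
    return ClimateStack(period_label, out)


def area_of(mask: np.ndarray, cell_area: float) -> float:
    """Area in km^2 covered by True cells of ``mask``."""
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    return float(np.count_nonzero(mask)) * cell_area


# ---------------------------------------------------------------------------
# I/O

_FORMATS = ("geotiff", "ascii_grid")
_EXT_FORMAT = {".tif": "geotiff", ".tiff": "geotiff", ".asc": "ascii_grid", ".txt": "ascii_grid"}


def _check_format(path: Path, fmt: str) -> None:
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    implied = _EXT_FORMAT.get(path.suffix.lower())
    if implied is not None and implied != fmt:
        warnings.warn(
            f"extension {path.suffix!r} suggests {implied}, but format flag "
            f"{fmt!r} wins",
            stacklevel=3,
        )


def read_grid(path: str | Path, format: str | None = None, crs_label: str = "") -> Grid:
    """Read a single-band raster as a :class:`Grid`.

    ``format`` defaults to the one implied by the file extension.
    """
    path = Path(path)
    if format is None:
        format = _EXT_FORMAT.get(path.suffix.lower())
        if format is None:
            raise GridFormatError(f"cannot infer format from {path.name!r}")
    _check_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "geotiff":
        return _read_geotiff(path, crs_label)
    return _read_ascii(path, crs_label)


def write_grid(grid: Grid, path: str | Path, format: str | None = None) -> None:
    """Write a grid; re-readable by :func:`read_grid` with equal values/mask."""
    path = Path(path)
    if format is None:
        format = _EXT_FORMAT.get(path.suffix.lower())
        if format is None:
            raise GridFormatError(f"cannot infer format from {path.name!r}")
    _check_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "geotiff":
        _write_geotiff(grid, path)
    else:
        _write_ascii(grid, path)


def _read_geotiff(path: Path, crs_label: str) -> Grid:
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray().astype(float)
            tags = page.tags
            scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
            tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
            nodata_tag = tags.get(_TAG_GDAL_NODATA)
            scale_value = None if scale is None else tuple(scale.value)
            tie_value = None if tiepoint is None else tuple(tiepoint.value)
            nodata_value = None if nodata_tag is None else str(nodata_tag.value)
    except (tifffile.TiffFileError, OSError) as exc:
        raise GridFormatError(f"not a readable TIFF: {path}") from exc
    if values.ndim != 2:
        raise GridFormatError("expected a single-band raster")
    if scale_value is None or tie_value is None:
        raise GridFormatError(f"missing georeferencing tags in {path}")
    sx, sy = float(scale_value[0]), float(scale_value[1])
    i, j, _, x, y, _ = (float(v) for v in tie_value[:6])
    # tiepoint maps raster (i, j) to model (x, y); we anchor at (0, 0)
    x_origin = x - i * sx
    y_origin = y + j * sy
    mask = ~np.isfinite(values)
    if nodata_value is not None:
        txt = nodata_value.strip().strip("\x00")
        try:
            nd = float(txt)
        except ValueError:
            nd = math.nan
        if math.isfinite(nd):
            mask |= values == nd
    return Grid(values, GridTransform(x_origin, y_origin, sx, -sy), mask, crs_label)


def _write_geotiff(grid: Grid, path: Path) -> None:
    data = grid.values.astype(np.float32)
    data[grid.nodata_mask] = np.nan
    t = grid.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.dx, -t.dy, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x_origin, t.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, "nan"),
    ]
    if grid.crs_label:
        extratags.append((270, "s", 0, grid.crs_label))  # ImageDescription
    try:
        tifffile.imwrite(path, data, extratags=extratags)
    except OSError as exc:
        raise OSError(f"failed to write {path}") from exc


_ASCII_NODATA = -9999.0


def _write_ascii(grid: Grid, path: Path) -> None:
    t = grid.transform
    if abs(t.dx + t.dy) > _ALIGN_TOL * t.dx:
        raise GridFormatError("ASCII grid requires square cells")
    nrows, ncols = grid.shape
    data = grid.values.copy()
    data[grid.nodata_mask] = _ASCII_NODATA
    header = (
        f"NCOLS {ncols}\n"
        f"NROWS {nrows}\n"
        f"XLLCORNER {t.x_origin:.17g}\n"
        f"YLLCORNER {t.y_origin + nrows * t.dy:.17g}\n"
        f"CELLSIZE {t.dx:.17g}\n"
        f"NODATA_value {_ASCII_NODATA:g}\n"
    )
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in data)
    path.write_text(header + body + "\n")


def _read_ascii(path: Path, crs_label: str) -> Grid:
    tokens: dict[str, float] = {}
    lines = path.read_text().splitlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].upper() in {
            "NCOLS", "NROWS", "XLLCORNER", "YLLCORNER", "CELLSIZE", "NODATA_VALUE",
        }:
            tokens[parts[0].upper()] = float(parts[1])
        else:
            break
    required = {"NCOLS", "NROWS", "XLLCORNER", "YLLCORNER", "CELLSIZE"}
    if not required <= tokens.keys():
        raise GridFormatError(f"incomplete ASCII grid header in {path}")
    ncols, nrows = int(tokens["NCOLS"]), int(tokens["NROWS"])
    nodata = tokens.get("NODATA_VALUE", _ASCII_NODATA)
    body = " ".join(lines[i:]).split()
    try:
        flat = np.array(body, dtype=float)
    except ValueError as exc:
        raise GridFormatError(f"non-numeric cell value in {path}") from exc
    if flat.size != nrows * ncols:
        raise GridFormatError(
            f"expected {nrows * ncols} values, found {flat.size} in {path}"
        )
    values = flat.reshape(nrows, ncols)
    mask = values == nodata
    cell = tokens["CELLSIZE"]
    transform = GridTransform(
        tokens["XLLCORNER"], tokens["YLLCORNER"] + nrows * cell, cell, -cell
    )
    return Grid(values, transform, mask, crs_label)
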