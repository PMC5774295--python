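"""Synthetic multi-period climate stacks with a known suitability truth.

The generator emulates the ingredients the pipeline needs from real
bioclimatic data: smooth large-scale gradients (temperature falling with
latitude, precipitation falling inland), spatially autocorrelated local
variation, strong cross-correlation between designated variable pairs
(e.g. mean annual temperature vs. minimum temperature of the coldest
month), period-to-period climate offsets (glacial cooling, future
warming), a logistic-linear ground-truth suitability function, and
spatially biased presence sampling.  Everything is deterministic given the
spec's seed.

Default conditions: a 120 x 120 grid of 10-km cells (a 1200-km square,
continental-subregion scale), six bioclim-style variables, four periods
(lig, lgm, present, f2080) whose offsets follow the glacial-interglacial
pattern (LGM roughly 5-8 degC colder and substantially drier than present,
2080 about 3 degC warmer), and 200 presences drawn with an eastern
sampling bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cholesky, solve_triangular, LinAlgError
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grids import ClimateStack, Grid, GridTransform, write_grid
from .occurrences import OccurrenceSet, SamplingError, write_occurrences

__all__ = [
    "SyntheticSpec",
    "SyntheticSpecError",
    "make_climate_series",
    "true_suitability",
    "make_bias_grid",
    "sample_occurrences",
    "write_fixture",
]


class SyntheticSpecError(ValueError):
    """The synthetic specification is inconsistent or unreachable."""


_DEFAULT_VARIABLES = ("bio1", "bio4", "bio6", "bio12", "bio14", "bio18")

# Domain-scale mean and spatial standard deviation of each variable
# (degC / dimensionless seasonality x100 / degC / mm / mm / mm).
_DEFAULT_MEANS = {"bio1": 14.0, "bio4": 800.0, "bio6": 0.0, "bio12": 1100.0, "bio14": 35.0, "bio18": 450.0}
_DEFAULT_SDS = {"bio1": 6.0, "bio4": 150.0, "bio6": 7.0, "bio12": 350.0, "bio14": 18.0, "bio18": 150.0}

# Direction in which each variable increases: angle in degrees clockwise
# from north.  Temperatures rise southwards, seasonality rises northwards,
# precipitation rises towards the southeast (a monsoon-like pattern).
_DEFAULT_GRADIENTS = {"bio1": 180.0, "bio4": 0.0, "bio6": 180.0, "bio12": 135.0, "bio14": 135.0, "bio18": 120.0}

# Additive per-period climate offsets relative to the present.
_DEFAULT_OFFSETS = {
    "lig": {"bio1": 1.5, "bio6": 2.0, "bio12": 50.0},
    "lgm": {"bio1": -5.5, "bio4": 150.0, "bio6": -8.0, "bio12": -300.0, "bio14": -10.0, "bio18": -80.0},
    "present": {},
    "f2080": {"bio1": 3.2, "bio4": -50.0, "bio6": 3.8, "bio12": 60.0, "bio14": -5.0, "bio18": 30.0},
}

# Ground truth: a warm, winter-mild, wet-adapted species with a dislike of
# high seasonality -- the profile of a mid-latitude mesic conifer.  The
# strongly negative intercept confines the range to a restricted fraction
# of the domain (~16% of cells at present), as befits a narrow-tolerance
# relict species.
_DEFAULT_COEFFICIENTS = {"bio1": 2.4, "bio4": -2.0, "bio6": 3.0, "bio12": 1.6, "bio14": 1.0}
_DEFAULT_INTERCEPT = -6.0


@dataclass
class SyntheticSpec:
    grid_shape: tuple[int, int] = (120, 120)
    cell_size_km: float = 10.0
    variables: tuple[str, ...] = _DEFAULT_VARIABLES
    var_means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    var_sds: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SDS))
    gradient_bearings: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_GRADIENTS))
    spatial_correlation_length: float = 50.0  # km; Gaussian smoothing scale
    gradient_weight: float = 0.7  # share of each field's sd carried by the gradient
    cross_correlation: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("bio1", "bio6"): 0.9}
    )
    periods: tuple[str, ...] = ("lig", "lgm", "present", "f2080")
    period_offsets: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_OFFSETS.items()}
    )
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COEFFICIENTS)
    )
    true_intercept: float = _DEFAULT_INTERCEPT
    bias_center_km: tuple[float, float] = (900.0, 600.0)  # (x, y) from SW corner
    bias_sd_km: float = 300.0
    n_presences: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        nr, nc = self.grid_shape
        if nr <= 0 or nc <= 0 or self.cell_size_km <= 0:
            raise SyntheticSpecError("grid_shape and cell size must be positive")
        if self.n_presences < 1:
            raise SyntheticSpecError("n_presences must be >= 1")
        for (a, b), r in self.cross_correlation.items():
            if not (a in self.variables and b in self.variables):
                raise SyntheticSpecError(f"cross-correlation names unknown variable: {(a, b)}")
            if abs(r) > 1:
                raise SyntheticSpecError(f"|cross_correlation| must be <= 1, got {r}")
        if not 0 <= self.gradient_weight <= 1:
            raise SyntheticSpecError("gradient_weight must be in [0, 1]")

    @property
    def transform(self) -> GridTransform:
        nr, _ = self.grid_shape
        cell_m = self.cell_size_km * 1000.0
        return GridTransform(0.0, nr * cell_m, cell_m, -cell_m)


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / (sd if sd > 0 else 1.0)


def make_climate_series(spec: SyntheticSpec) -> list[ClimateStack]:
    """Generate one aligned ClimateStack per period.

    Each variable is a smooth directional gradient plus spatially
    autocorrelated Gaussian noise; the set of standardized fields is
    whitened and re-coloured so designated pairs attain their target
    Pearson correlation exactly, then scaled to the variable's mean/sd and
    shifted by its period offset.  Periods share the same base fields, so a
    zero offset means identical stacks.
    """
    nr, nc = spec.grid_shape
    rng = np.random.default_rng(spec.seed)
    rows, cols = np.indices((nr, nc))
    # km coordinates of cell centres, y measured northward from the SW corner
    x = (cols + 0.5) * spec.cell_size_km
    y = (nr - rows - 0.5) * spec.cell_size_km

    sigma_cells = spec.spatial_correlation_length / spec.cell_size_km
    gw = spec.gradient_weight
    fields = []
    for name in spec.variables:
        theta = np.deg2rad(spec.gradient_bearings.get(name, 0.0))
        grad = _standardize(x * np.sin(theta) + y * np.cos(theta))
        noise = _standardize(gaussian_filter(rng.standard_normal((nr, nc)), sigma_cells))
        fields.append(_standardize(gw * grad + np.sqrt(1 - gw**2) * noise))

    k = len(spec.variables)
    target = np.eye(k)
    idx = {n: i for i, n in enumerate(spec.variables)}
    for (a, b), r in spec.cross_correlation.items():
        target[idx[a], idx[b]] = target[idx[b], idx[a]] = r
    try:
        l_target = cholesky(target, lower=True)
    except LinAlgError as exc:
        raise SyntheticSpecError("cross-correlation targets are not jointly reachable") from exc

    z = np.column_stack([f.ravel() for f in fields])
    z -= z.mean(axis=0)
    z /= z.std(axis=0)
    emp = (z.T @ z) / len(z)
    c_emp = cholesky(emp, lower=True)
    white = solve_triangular(c_emp, z.T, lower=True).T  # empirically uncorrelated
    coloured = white @ l_target.T  # empirical correlation == target

    transform = spec.transform
    stacks = []
    for period in spec.periods:
        offsets = spec.period_offsets.get(period, {})
        grids = {}
        for i, name in enumerate(spec.variables):
            vals = (
                spec.var_means[name]
                + spec.var_sds[name] * coloured[:, i].reshape(nr, nc)
                + offsets.get(name, 0.0)
            )
            grids[name] = Grid(vals, transform, np.zeros((nr, nc), dtype=bool), "synthetic")
        stacks.append(ClimateStack(period, grids))
    return stacks


def true_suitability(stack: ClimateStack, spec: SyntheticSpec) -> Grid:
    """Ground-truth suitability: logistic of a linear predictor.

    Variables are standardized with the spec's *fixed* reference means and
    sds (not per-stack), so period offsets genuinely move suitability.
    """
    eta = np.full(stack.template.shape, spec.true_intercept, dtype=float)
    for name, w in spec.true_coefficients.items():
        if name not in stack.variables:
            raise SyntheticSpecError(f"truth coefficient names missing variable {name!r}")
        z = (stack[name].values - spec.var_means[name]) / spec.var_sds[name]
        eta += w * z
    p = expit(eta)
    mask = stack.mask
    p = np.where(mask, np.nan, p)
    return stack.template.like(p, mask.copy())


def make_bias_grid(template: Grid, spec: SyntheticSpec) -> Grid:
    """The generating sampling-bias kernel (not the estimated one)."""
    xs, ys = template.cell_centers()
    cx, cy = (v * 1000.0 for v in spec.bias_center_km)
    sd = spec.bias_sd_km * 1000.0
    b = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sd**2))
    b = np.where(template.nodata_mask, np.nan, b)
    return template.like(b)


def sample_occurrences(truth: Grid, bias: Grid, n: int, seed: int) -> OccurrenceSet:
    """Draw ``n`` distinct presence cells with probability ~ truth x bias."""
    if truth.shape != bias.shape or not truth.transform.close_to(bias.transform):
        raise ValueError("truth and bias grids are not aligned")
    mask = truth.nodata_mask | bias.nodata_mask
    w = np.where(mask, 0.0, np.nan_to_num(truth.values) * np.nan_to_num(bias.values))
    w = np.clip(w, 0.0, None)
    flat = w.ravel()
    positive = np.flatnonzero(flat > 0)
    if len(positive) < n:
        raise SamplingError(
            f"requested {n} presences but only {len(positive)} cells have positive weight"
        )
    rng = np.random.default_rng(seed)
    picked = positive[rng.choice(len(positive), size=n, replace=False, p=flat[positive] / flat[positive].sum())]
    rows, cols = np.unravel_index(picked, truth.shape)
    x, y = truth.transform.cell_center(rows, cols)
    ids = [f"occ{i + 1:04d}" for i in range(n)]
    return OccurrenceSet(ids, np.column_stack([x, y]), "synthetic")


def write_fixture(spec: SyntheticSpec, outdir: str | Path, format: str = "ascii_grid") -> dict:
    """Materialize the synthetic study on disk in pipeline-ready layout.

    Writes one subdirectory of rasters per period plus ``occurrences.csv``;
    returns the paths.  The presence sample is drawn from the *present*
    period's truth under the spec's bias kernel.
    """
    outdir = Path(outdir)
    ext = ".asc" if format == "ascii_grid" else ".tif"
    stacks = make_climate_series(spec)
    paths: dict = {"stack_dirs": {}, "occurrences": None}
    for stack in stacks:
        d = outdir / stack.period_label
        for name, grid in stack.variables.items():
            write_grid(grid, d / f"{name}{ext}", format)
        paths["stack_dirs"][stack.period_label] = d
    by_label = {s.period_label: s for s in stacks}
    train = by_label.get("present", stacks[-1])
    truth = true_suitability(train, spec)
    bias = make_bias_grid(train.template, spec)
    occ = sample_occurrences(truth, bias, spec.n_presences, spec.seed)
    occ_path = outdir / "occurrences.csv"
    write_occurrences(occ, occ_path)
    paths["occurrences"] = occ_path
    return paths
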