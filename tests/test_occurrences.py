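import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chisquare

from rangeshift.occurrences import (
    OccurrenceSet,
    SamplingError,
    SchemaError,
    bias_surface,
    read_occurrences,
    sample_background,
    thin,
)
from .conftest import make_grid


def occ_at(points_km, prefix="p"):
    xy = np.asarray(points_km, dtype=float) * 1000.0
    return OccurrenceSet([f"{prefix}{i:02d}" for i in range(len(xy))], xy)


def brute_force_max_thin(xy_m: np.ndarray, min_dist_m: float) -> int:
    """Exhaustive maximum independent set size on the conflict graph."""
    n = len(xy_m)
    d = squareform(pdist(xy_m)) if n > 1 else np.zeros((1, 1))
    best = 0
    for r in range(n, 0, -1):
        if r <= best:
            break
        for subset in itertools.combinations(range(n), r):
            sub = d[np.ix_(subset, subset)]
            if np.all(sub[np.triu_indices(r, 1)] >= min_dist_m):
                best = r
                break
    return best


# ---------------------------------------------------------------------------
# CSV ingestion


def test_read_occurrences_parses_all_rows(tmp_path):
    p = tmp_path / "occ.csv"
    p.write_text("id,x,y\na,0,0\nb,1000,2000\nc,5,5\n")
    occ = read_occurrences(p)
    assert len(occ) == 3 and occ.ids == ["a", "b", "c"]


def test_read_occurrences_schema_and_parse_errors(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("id,x\na,0\n")
    with pytest.raises(SchemaError, match="y"):
        read_occurrences(p)
    p.write_text("id,x,y\na,0,north\n")
    with pytest.raises(ValueError, match="non-numeric"):
        read_occurrences(p)
    p.write_text("id,x,y\na,0,0\na,1,1\n")
    with pytest.raises(SchemaError, match="duplicate"):
        read_occurrences(p)


# ---------------------------------------------------------------------------
# Thinning


def test_thin_collinear_points_keeps_the_two_ends():
    occ = occ_at([[0, 0], [6, 0], [12, 0]])
    kept = thin(occ, 10.0)
    assert kept.ids == ["p00", "p02"]


def test_thin_returns_input_when_no_conflicts():
    occ = occ_at([[0, 0], [50, 0], [0, 50]])
    assert thin(occ, 10.0).ids == occ.ids


def test_thin_is_empty_on_empty_input():
    assert len(thin(OccurrenceSet([], np.empty((0, 2))), 10.0)) == 0


def test_thin_tie_break_prefers_earlier_ids():
    occ = occ_at([[0, 0], [5, 0]])
    assert thin(occ, 10.0).ids == ["p00"]


def test_thin_matches_exhaustive_oracle_on_small_instances():
    for trial in range(25):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 13))
        xy = rng.uniform(0, 50_000.0, size=(n, 2))
        occ = OccurrenceSet([f"q{i:02d}" for i in range(n)], xy)
        dists = pdist(xy)
        min_dist_m = float(np.percentile(dists, 30))
        if min_dist_m <= 0:
            continue
        kept = thin(occ, min_dist_m / 1000.0)
        assert len(kept) == brute_force_max_thin(xy, min_dist_m)
        if len(kept) > 1:
            assert pdist(kept.xy).min() >= min_dist_m


def test_thin_output_never_exceeds_input():
    rng = np.random.default_rng(42)
    xy = rng.uniform(0, 30_000.0, size=(20, 2))
    occ = OccurrenceSet([f"r{i:02d}" for i in range(20)], xy)
    kept = thin(occ, 8.0)
    assert len(kept) <= len(occ)


# ---------------------------------------------------------------------------
# Bias surface


def test_bias_surface_peaks_at_single_point():
    template = make_grid(np.zeros((21, 21)), cell_m=10_000.0)
    x, y = template.transform.cell_center(10, 10)
    surface = bias_surface(occ_from_xy([[x, y]]), template, radius_km=60.0)
    assert surface.values[10, 10] == pytest.approx(1.0)
    assert np.nanargmax(surface.values) == 10 * 21 + 10


def occ_from_xy(xy_m):
    xy_m = np.asarray(xy_m, dtype=float)
    return OccurrenceSet([f"s{i}" for i in range(len(xy_m))], xy_m)


def test_bias_surface_value_at_sigma_is_exp_minus_half():
    template = make_grid(np.zeros((21, 21)), cell_m=10_000.0)
    x, y = template.transform.cell_center(10, 10)
    surface = bias_surface(occ_from_xy([[x, y]]), template, radius_km=60.0)
    # cell 6 cells east = exactly sigma = 60 km away
    assert surface.values[10, 16] == pytest.approx(np.exp(-0.5), rel=1e-9)
    # beyond the 3-sigma truncation the kernel is exactly zero
    far = make_grid(np.zeros((41, 41)), cell_m=10_000.0)
    x, y = far.transform.cell_center(20, 20)
    s2 = bias_surface(occ_from_xy([[x, y]]), far, radius_km=30.0)
    assert s2.values[20, 40] == 0.0  # 200 km > 3 x 30 km


def test_bias_surface_mirror_symmetry():
    template = make_grid(np.zeros((20, 20)), cell_m=10_000.0)
    xa, ya = template.transform.cell_center(5, 3)
    xb, yb = template.transform.cell_center(14, 16)  # mirror through the centre
    surface = bias_surface(occ_from_xy([[xa, ya], [xb, yb]]), template, 60.0)
    assert np.allclose(surface.values, surface.values[::-1, ::-1], atol=1e-12)


def test_bias_surface_without_points_is_uniform_one():
    mask = np.zeros((5, 5), dtype=bool)
    mask[0, 0] = True
    template = make_grid(np.zeros((5, 5)), mask=mask)
    surface = bias_surface(occ_from_xy(np.empty((0, 2))), template, 60.0)
    assert np.all(surface.values[~mask] == 1.0)
    assert surface.nodata_mask[0, 0] and np.isnan(surface.values[0, 0])


def test_bias_surface_translation_equivariance():
    template = make_grid(np.zeros((30, 30)), cell_m=10_000.0)
    x, y = template.transform.cell_center(14, 14)
    a = bias_surface(occ_from_xy([[x, y]]), template, 40.0)
    b = bias_surface(occ_from_xy([[x + 10_000.0, y]]), template, 40.0)
    # interior: surface shifts by exactly one cell eastward
    assert np.allclose(a.values[:, 5:-6], b.values[:, 6:-5], atol=1e-12)


# ---------------------------------------------------------------------------
# Background sampling


def test_background_uniform_bias_frequencies_are_uniform():
    bias = make_grid(np.ones((5, 5)))
    counts = np.zeros(25)
    reps, n_draw = 2000, 5
    for seed in range(reps):
        bg = sample_background(bias, n_draw, seed)
        for r, c in bg.cells:
            counts[r * 5 + c] += 1
    stat = chisquare(counts)
    assert stat.pvalue > 1e-3


def test_background_single_positive_cell():
    vals = np.zeros((4, 4))
    vals[2, 3] = 5.0
    bg = sample_background(make_grid(vals), 1, seed=0)
    assert tuple(bg.cells[0]) == (2, 3)


def test_background_deterministic_and_errors():
    bias = make_grid(np.ones((4, 4)))
    a = sample_background(bias, 6, seed=11)
    b = sample_background(bias, 6, seed=11)
    assert np.array_equal(a.xy, b.xy)
    with pytest.raises(SamplingError):
        sample_background(bias, 17, seed=0)


def test_background_respects_exclusion():
    bias = make_grid(np.ones((3, 3)))
    x, y = bias.transform.cell_center(1, 1)
    bg = sample_background(bias, 8, seed=0, exclude=occ_from_xy([[x, y]]))
    assert (1, 1) not in {tuple(c) for c in bg.cells}
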