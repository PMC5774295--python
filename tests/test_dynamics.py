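import numpy as np
import pytest

from rangeshift.dynamics import (
    CONTRACTION,
    EXPANSION,
    NO_CHANGE,
    ABSENT,
    BinaryMap,
    CentroidError,
    MatchingError,
    binarize,
    block_centroids,
    centroid_vector,
    change_map,
    change_ratios,
    change_table,
    migration_vectors,
    mtss_threshold,
    overall_centroid,
    round_half_away,
    ten_percent_tp_threshold,
)
from .conftest import make_grid


def bmap(bool_array, label="p", cell_m=10_000.0):
    arr = np.asarray(bool_array, dtype=bool)
    return BinaryMap(arr, 0.5, label, make_grid(np.zeros(arr.shape), cell_m=cell_m))


def mtss_brute_force(sp, sb):
    cands = np.unique(np.concatenate([sp, sb]))
    best_t, best_v = None, -1.0
    for t in cands:
        v = np.mean(sp >= t) + np.mean(sb < t)
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return best_t


# ---------------------------------------------------------------------------
# Thresholds


def test_mtss_perfect_separation_picks_smallest_maximizer():
    assert mtss_threshold([0.9, 0.8], [0.1, 0.2]) == 0.8


def test_mtss_four_candidate_case_matches_brute_force():
    # scanning all 4 candidates: sens+spec peaks at 1.5 for both t=0.3 and
    # t=0.7; the smallest maximizer wins
    sp = np.array([0.7, 0.3])
    sb = np.array([0.5, 0.1])
    assert mtss_threshold(sp, sb) == mtss_brute_force(sp, sb) == 0.3


def test_mtss_all_scores_equal():
    assert mtss_threshold([0.4, 0.4], [0.4, 0.4]) == 0.4


def test_mtss_matches_exhaustive_scan_on_random_inputs():
    rng = np.random.default_rng(11)
    for _ in range(20):
        sp = rng.choice(np.round(np.linspace(0, 1, 41), 3), size=rng.integers(1, 250))
        sb = rng.choice(np.round(np.linspace(0, 1, 41), 3), size=rng.integers(1, 250))
        assert mtss_threshold(sp, sb) == mtss_brute_force(sp, sb)


def test_ten_percent_tp_order_statistic():
    assert ten_percent_tp_threshold(np.arange(0.1, 1.05, 0.1)) == pytest.approx(0.2)
    assert ten_percent_tp_threshold([0.5, 0.9, 0.2, 0.7, 0.4]) == 0.2  # m=5: minimum
    assert ten_percent_tp_threshold([0.3, 0.3, 0.3]) == 0.3


# ---------------------------------------------------------------------------
# Binarization


def test_binarize_boundary_and_extremes():
    vals = np.array([[0.2, 0.5], [0.8, 0.5]])
    grid = make_grid(vals)
    assert binarize(grid, 0.0).suitable.all()
    assert not binarize(grid, 0.80001).suitable.any()
    assert binarize(grid, 0.5).suitable[0, 1]  # score == threshold is suitable


def test_binarize_is_monotone_in_threshold():
    rng = np.random.default_rng(3)
    grid = make_grid(rng.uniform(size=(20, 20)))
    low, high = binarize(grid, 0.3), binarize(grid, 0.7)
    assert np.all(high.suitable <= low.suitable)


def test_binarize_never_marks_masked_cells():
    mask = np.zeros((3, 3), dtype=bool)
    mask[1, 1] = True
    grid = make_grid(np.ones((3, 3)), mask=mask)
    assert not binarize(grid, 0.5).suitable[1, 1]


# ---------------------------------------------------------------------------
# Change map / table


def test_change_map_hand_built_labels():
    early = bmap([[1, 1, 0], [1, 0, 0], [0, 0, 0]])
    late = bmap([[1, 0, 1], [0, 1, 1], [0, 0, 0]])
    cmap = change_map(early, late)
    assert cmap.classes[0, 0] == NO_CHANGE
    assert cmap.classes[0, 1] == CONTRACTION and cmap.classes[1, 0] == CONTRACTION
    assert {tuple(c) for c in np.argwhere(cmap.classes == EXPANSION)} == {
        (0, 2), (1, 1), (1, 2)}
    assert cmap.classes[2, 2] == ABSENT


def test_identical_maps_have_only_no_change_and_absent():
    m = bmap([[1, 0], [0, 1]])
    cmap = change_map(m, bmap([[1, 0], [0, 1]]))
    assert set(np.unique(cmap.classes)) <= {ABSENT, NO_CHANGE}
    table = change_table(cmap)
    assert table.areas["contraction"] == 0.0 and table.areas["expansion"] == 0.0
    assert table.ratio_no_change == 100.0


def test_empty_early_makes_every_late_cell_expansion():
    early = bmap(np.zeros((3, 3)))
    late = bmap([[0, 1, 0], [0, 1, 0], [0, 0, 0]])
    cmap = change_map(early, late)
    assert (cmap.classes == EXPANSION).sum() == 2
    table = change_table(cmap)
    assert table.ratio_contraction is None  # early area zero: undefined, not 0
    assert table.ratio_expansion == 100.0


def test_change_table_identities_hold_exactly():
    rng = np.random.default_rng(5)
    early = bmap(rng.random((15, 15)) > 0.5)
    late = bmap(rng.random((15, 15)) > 0.6)
    table = change_table(change_map(early, late))
    assert table.area_early == pytest.approx(early.area_km2)
    assert table.area_late == pytest.approx(late.area_km2)
    assert table.areas["contraction"] + table.areas["no_change"] == table.area_early
    assert table.areas["no_change"] + table.areas["expansion"] == table.area_late


@pytest.mark.parametrize(
    "x,expected",
    [(0.05, 0.1), (-0.05, -0.1), (2.25, 2.3), (16.738, 16.7), (42.011, 42.0)],
)
def test_round_half_away(x, expected):
    assert round_half_away(x, 1) == expected


# ---------------------------------------------------------------------------
# Centroids and vectors


def test_overall_centroid_examples():
    single = bmap([[0, 0], [1, 0]])
    x, y = single.grid.transform.cell_center(1, 0)
    assert overall_centroid(single) == (x, y)

    sym = bmap([[1, 0, 0], [0, 0, 0], [0, 0, 1]])
    cx, cy = overall_centroid(sym)
    assert cx == pytest.approx(15_000.0) and cy == pytest.approx(15_000.0)

    lshape = bmap([[1, 0], [1, 1]])
    pts = [lshape.grid.transform.cell_center(r, c) for r, c in [(0, 0), (1, 0), (1, 1)]]
    assert overall_centroid(lshape) == (
        pytest.approx(np.mean([p[0] for p in pts])),
        pytest.approx(np.mean([p[1] for p in pts])),
    )
    with pytest.raises(CentroidError):
        overall_centroid(bmap(np.zeros((2, 2))))


def test_centroid_vector_shift_and_bearing():
    base = np.zeros((20, 20), dtype=bool)
    base[10:14, 5:9] = True
    early = bmap(base)
    north = bmap(np.roll(base, -5, axis=0))  # 5 cells north = 50 km
    v = centroid_vector(early, north).vectors[0]
    assert v.distance_km == pytest.approx(50.0)
    assert v.bearing_deg == pytest.approx(0.0)

    both = bmap(np.roll(np.roll(base, -4, axis=0), 3, axis=1))  # 3 east, 4 north
    v2 = centroid_vector(early, both).vectors[0]
    assert v2.distance_km == pytest.approx(50.0)
    assert v2.bearing_deg == pytest.approx(np.degrees(np.arctan2(3, 4)))

    same = centroid_vector(early, bmap(base)).vectors[0]
    assert same.distance_km == 0.0


def test_block_centroids_examples():
    arr = np.zeros((12, 12), dtype=bool)
    arr[2, 3] = True
    single = bmap(arr)
    cents = block_centroids(single, block_km=60.0)
    assert cents == [single.grid.transform.cell_center(2, 3)]

    full = np.zeros((12, 12), dtype=bool)
    full[0:6, 0:6] = True  # exactly one 60 km tile fully suitable
    cents = block_centroids(bmap(full), block_km=60.0)
    assert cents == [(pytest.approx(30_000.0), pytest.approx(120_000.0 - 30_000.0))]

    two = np.zeros((12, 12), dtype=bool)
    two[0, 0] = two[0, 1] = True  # tile (0,0): two cells
    two[7, 7] = True  # tile (1,1): one cell
    t = bmap(two)
    cents = block_centroids(t, block_km=60.0)
    c1 = t.grid.transform.cell_center(0, 0)
    c2 = t.grid.transform.cell_center(0, 1)
    expect1 = ((c1[0] + c2[0]) / 2, (c1[1] + c2[1]) / 2)
    assert cents[0] == (pytest.approx(expect1[0]), pytest.approx(expect1[1]))
    assert cents[1] == t.grid.transform.cell_center(7, 7)
    assert block_centroids(bmap(np.zeros((12, 12))), 60.0) == []


def test_migration_vectors_translation_recovery():
    # well-separated patches translated 70 km north
    early_pts = [(200_000.0, 200_000.0), (500_000.0, 400_000.0), (900_000.0, 150_000.0)]
    late_pts = [(x, y + 70_000.0) for x, y in early_pts]
    field = migration_vectors(early_pts, late_pts)
    assert len(field) == 3 and not field.unmatched_sources
    for v in field.vectors:
        assert v.distance_km == pytest.approx(70.0)
        assert v.bearing_deg == pytest.approx(0.0)


def test_migration_vectors_identity_and_unmatched():
    pts = [(0.0, 0.0), (300_000.0, 0.0)]
    field = migration_vectors(pts, pts)
    assert all(v.distance_km == 0.0 for v in field.vectors)
    field2 = migration_vectors(pts, [(1_000.0, 0.0)])
    assert len(field2) == 1
    assert field2.vectors[0].source == (0.0, 0.0)
    assert field2.unmatched_sources == [(300_000.0, 0.0)]
    with pytest.raises(MatchingError):
        migration_vectors([], pts)
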