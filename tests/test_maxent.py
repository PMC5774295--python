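import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from rangeshift.grids import build_stack
from rangeshift.maxent import (
    MaxentModel,
    build_features,
    evaluate_auc,
    fit_maxent,
    predict_logistic,
    replicate_runs,
)
from rangeshift.occurrences import OccurrenceSet
from .conftest import make_grid


def auc_pair_counting(sp, sb):
    """O(n^2) oracle: wins + half-ties over all presence/background pairs."""
    wins = sum((p > b) + 0.5 * (p == b) for p in sp for b in sb)
    return wins / (len(sp) * len(sb))


# ---------------------------------------------------------------------------
# Features


def test_feature_values_at_bounds_and_knots():
    vals = np.array([[0.0], [5.0], [10.0]])
    fs, design = build_features(vals, ["v"], n_hinge_knots=2)
    cols = {f: i for i, f in enumerate(fs.feature_index)}
    lin = design[:, cols[("linear", "v", None)]]
    quad = design[:, cols[("quadratic", "v", None)]]
    hinge_mid = design[:, cols[("hinge", "v", 5.0)]]
    assert lin[0] == 0.0 and lin[2] == 1.0
    assert quad[2] == 1.0 and quad[1] == pytest.approx(0.25)
    assert hinge_mid[1] == 0.0 and hinge_mid[2] == 1.0
    assert design.min() >= 0.0 and design.max() <= 1.0


def test_constant_variable_features_dropped_with_warning():
    vals = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
    with pytest.warns(UserWarning, match="constant"):
        fs, design = build_features(vals, ["a", "flat"])
    assert fs.dropped == ["flat"]
    assert all(name != "flat" for _, name, _ in fs.feature_index)


# ---------------------------------------------------------------------------
# Fitting


def test_constant_feature_yields_uniform_model():
    pres = np.full((10, 1), 0.5)
    bg = np.full((100, 1), 0.5)
    model = fit_maxent(pres, bg)
    assert np.all(model.lambdas == 0.0)
    assert model.entropy == pytest.approx(np.log(100))
    assert np.allclose(model.raw(bg), 1 / 100)
    assert np.allclose(model.logistic(bg), 0.5)


def test_binary_feature_fit_matches_1d_oracle():
    m, n = 20, 100
    pres = np.ones((m, 1))
    bg = np.zeros((n, 1))
    bg[: n // 2] = 1.0
    beta_j = max(pres.std(), 0.05 * 1.0) / np.sqrt(m)  # same penalty rule

    def neg_penalized(lam):
        log_z = logsumexp(np.array([lam] * (n // 2) + [0.0] * (n // 2)))
        return -(lam - log_z - beta_j * abs(lam))

    oracle = minimize_scalar(neg_penalized, bounds=(0, 20), method="bounded",
                             options={"xatol": 1e-10})
    with pytest.warns(UserWarning, match="background"):
        model = fit_maxent(pres, bg)
    assert model.lambdas[0] == pytest.approx(oracle.x, abs=1e-4)
    assert model.objective_history[-1] == pytest.approx(-oracle.fun, abs=1e-8)


def test_background_raw_distribution_normalizes(fitted, present_stack, study):
    model = fitted["model"]
    bg_vals = present_stack.values_at(
        study["background"].xy[:, 0], study["background"].xy[:, 1],
        model.features.var_names,
    )
    q = model.raw(model.features.transform(bg_vals))
    assert q.sum() == pytest.approx(1.0, abs=1e-8)


def test_objective_history_is_nondecreasing(fitted):
    h = np.asarray(fitted["model"].objective_history)
    assert np.all(np.diff(h) >= -1e-9)


def test_huge_beta_drives_model_to_uniform(present_stack, study):
    names = present_stack.names
    occ, bg = study["occ"], study["background"]
    pres_vals = present_stack.values_at(occ.xy[:, 0], occ.xy[:, 1], names)
    bg_vals = present_stack.values_at(bg.xy[:, 0], bg.xy[:, 1], names)
    fs, bg_design = build_features(bg_vals, names)
    model = fit_maxent(fs.transform(pres_vals), bg_design, beta=1e6, feature_set=fs)
    assert np.all(model.lambdas == 0.0)
    assert np.allclose(model.logistic(bg_design), 0.5)


def test_model_json_round_trip(fitted, present_stack):
    model = fitted["model"]
    clone = MaxentModel.from_json(model.to_json())
    vals = present_stack.values_matrix(model.features.var_names)[:500]
    assert np.allclose(clone.predict_values(vals), model.predict_values(vals))


# ---------------------------------------------------------------------------
# Prediction / clamping


def test_zero_lambda_model_predicts_half_everywhere(present_stack):
    names = present_stack.names
    bg_vals = present_stack.values_matrix(names)[:200]
    fs, design = build_features(bg_vals, names)
    model = fit_maxent(np.full((5, design.shape[1]), design.mean()), design, beta=1e9,
                       feature_set=fs)
    pred = predict_logistic(model, present_stack)
    assert np.allclose(pred.values[~pred.nodata_mask], 0.5)


def test_clamped_prediction_saturates_beyond_training_max(fitted):
    model = fitted["model"]
    names = model.features.var_names
    at_max = np.array([[model.features.bounds[n][1] for n in names]])
    beyond = at_max + 100.0
    assert model.predict_values(beyond, clamp=True) == pytest.approx(
        model.predict_values(at_max, clamp=True)
    )


def test_prediction_consistent_across_stacks(fitted, present_stack):
    # the same cell values give the same score however they are delivered
    model = fitted["model"]
    sub = build_stack(
        {n: present_stack[n] for n in model.features.var_names}, "copy"
    )
    a = predict_logistic(model, present_stack)
    b = predict_logistic(model, sub)
    assert np.array_equal(a.values[~a.nodata_mask], b.values[~b.nodata_mask])


# ---------------------------------------------------------------------------
# AUC


def test_auc_examples():
    assert evaluate_auc([0.9, 0.8], [0.1, 0.2]) == 1.0
    assert evaluate_auc([0.3, 0.7], [0.3, 0.7]) == 0.5
    assert evaluate_auc([0.8, 0.4], [0.6, 0.2]) == 0.75


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(7)
    for _ in range(10):
        sp = rng.choice(np.linspace(0, 1, 21), size=rng.integers(2, 40))
        sb = rng.choice(np.linspace(0, 1, 21), size=rng.integers(2, 60))
        assert evaluate_auc(sp, sb) == pytest.approx(auc_pair_counting(sp, sb))


# ---------------------------------------------------------------------------
# Replicates


def test_split_arithmetic_8_presences():
    rng = np.random.default_rng(0)
    grid_vals = rng.uniform(size=(12, 12))
    stack = build_stack({"v": make_grid(grid_vals)}, "p")
    cells = [(r, r) for r in range(8)]
    x, y = zip(*(stack.template.transform.cell_center(r, c) for r, c in cells))
    occ = OccurrenceSet([f"w{i}" for i in range(8)], np.column_stack([x, y]))
    from rangeshift.occurrences import sample_background

    bg = sample_background(make_grid(np.ones((12, 12))), 100, 0)
    report, _ = replicate_runs(occ, bg, stack, k=1, train_fraction=0.75, seed=0)
    assert report.replicates.loc[0, "n_train"] == 6
    assert report.replicates.loc[0, "n_test"] == 2


def test_replicates_deterministic_given_seed(present_stack, study):
    a, _ = replicate_runs(study["occ"], study["background"], present_stack, k=2, seed=5)
    b, _ = replicate_runs(study["occ"], study["background"], present_stack, k=2, seed=5)
    assert a.replicates.equals(b.replicates)


def test_too_small_training_split_is_an_error(present_stack, study):
    tiny = study["occ"].subset(range(2))
    with pytest.raises(ValueError, match="too small"):
        replicate_runs(tiny, study["background"], present_stack, k=1, train_fraction=0.5)


def test_mean_test_auc_exceeds_0_8_on_default_synthetic_study(fitted):
    assert fitted["report"].mean_test_auc > 0.8
    assert 0.0 <= fitted["report"].mean_test_auc <= 1.0
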