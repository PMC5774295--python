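import numpy as np
import pytest

from rangeshift.grids import Grid, GridTransform
from rangeshift.maxent import predict_logistic, replicate_runs
from rangeshift.occurrences import sample_background
from rangeshift.synthetic import (
    SyntheticSpec,
    make_bias_grid,
    make_climate_series,
    sample_occurrences,
    true_suitability,
)


def make_grid(values, cell_m=10_000.0, x0=0.0, y0=None, mask=None):
    """Small Grid factory: row 0 north, square cells."""
    values = np.asarray(values, dtype=float)
    nr = values.shape[0]
    if y0 is None:
        y0 = nr * cell_m
    return Grid(values, GridTransform(x0, y0, cell_m, -cell_m), mask)


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def climate_series(default_spec):
    return make_climate_series(default_spec)


@pytest.fixture(scope="session")
def present_stack(climate_series):
    return next(s for s in climate_series if s.period_label == "present")


@pytest.fixture(scope="session")
def present_truth(present_stack, default_spec):
    return true_suitability(present_stack, default_spec)


@pytest.fixture(scope="session")
def study(default_spec, present_stack, present_truth):
    """Occurrences + bias-weighted background under the generating bias."""
    bias = make_bias_grid(present_stack.template, default_spec)
    occ = sample_occurrences(present_truth, bias, default_spec.n_presences, 1)
    background = sample_background(bias, 5000, 2)
    return {"bias": bias, "occ": occ, "background": background}


@pytest.fixture(scope="session")
def fitted(default_spec, present_stack, study):
    """Replicate-run evaluation and a final model on the default synthetic study."""
    report, model = replicate_runs(
        study["occ"], study["background"], present_stack, k=10, seed=3
    )
    prediction = predict_logistic(model, present_stack)
    return {"report": report, "model": model, "prediction": prediction}
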