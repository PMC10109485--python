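"""Latin hypercube sampling, the RBF surrogate, and the error metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from moxiopt.doe import (
    DesignTable,
    SurrogateModel,
    evaluate_responses,
    fit_metrics,
    latin_hypercube,
    train_rbnn,
)
from moxiopt.intervals import Box, interval_from_bounds
from moxiopt.synthetic import DESIGN_DOMAIN, design_domain_box

UNIT4 = Box([interval_from_bounds(0.0, 1.0)] * 4)


# ---------------------------------------------------------------------------
# Latin hypercube
# ---------------------------------------------------------------------------

def test_latin_property_exact_strata_occupancy():
    """50 points, 4 dims: every column hits each of the 50 equal strata once."""
    design = latin_hypercube(50, design_domain_box(), seed=42, names=tuple(DESIGN_DOMAIN))
    assert design.n == 50
    assert design.is_latin()
    lo = np.asarray(design.domain.lower)
    hi = np.asarray(design.domain.upper)
    assert np.all(design.values >= lo) and np.all(design.values <= hi)


def test_latin_hypercube_deterministic():
    a = latin_hypercube(20, UNIT4, seed=7)
    b = latin_hypercube(20, UNIT4, seed=7)
    assert np.array_equal(a.values, b.values)
    c = latin_hypercube(20, UNIT4, seed=8)
    assert not np.array_equal(a.values, c.values)


def test_maximin_optimization_improves_first_candidate():
    plain = latin_hypercube(30, UNIT4, seed=3, optimize=False)
    best = latin_hypercube(30, UNIT4, seed=3, optimize=True, candidates=50)
    assert pdist(best.values).min() >= pdist(plain.values).min()


def test_latin_hypercube_rejects_tiny_designs():
    with pytest.raises(ValueError):
        latin_hypercube(1, UNIT4, seed=0)


# ---------------------------------------------------------------------------
# response evaluation
# ---------------------------------------------------------------------------

def test_evaluate_responses_basic(pseudo_sim):
    design = latin_hypercube(3, design_domain_box(), seed=1, names=tuple(DESIGN_DOMAIN))
    table = evaluate_responses(design, pseudo_sim)
    assert len(table) == 3
    assert np.all(np.isfinite(table[["HPM", "ST"]].to_numpy()))


def test_evaluate_responses_constant_simulator():
    design = latin_hypercube(5, UNIT4, seed=2)
    table = evaluate_responses(design, lambda *args: (40.0, 50.0))
    assert (table["HPM"] == 40.0).all() and (table["ST"] == 50.0).all()


def test_evaluate_responses_flags_failures_and_aborts_on_many():
    design = latin_hypercube(10, UNIT4, seed=2)

    calls = {"n": 0}

    def flaky(*args):
        calls["n"] += 1
        if calls["n"] == 1:
            raise RuntimeError("boom")
        return (40.0, 50.0)

    table = evaluate_responses(design, flaky)
    assert table["status"].str.startswith("failed").sum() == 1
    assert table["HPM"].isna().sum() == 1

    with pytest.raises(RuntimeError, match="failed"):
        evaluate_responses(design, lambda *a: (_ for _ in ()).throw(RuntimeError("x")))


# ---------------------------------------------------------------------------
# RBF surrogate
# ---------------------------------------------------------------------------

def test_rbf_interpolates_training_points(pseudo_sim):
    design = latin_hypercube(30, design_domain_box(), seed=5, names=tuple(DESIGN_DOMAIN))
    responses = evaluate_responses(design, pseudo_sim)
    model = train_rbnn(design, responses)
    pred = model.predict(design.values)
    assert np.max(np.abs(pred - responses[["HPM", "ST"]].to_numpy())) < 1e-8


def test_rbf_generalizes_on_smooth_function():
    """Held-out R^2 >= 0.99 for f(x) = sum x_i^2 from 50 LHS points, and
    doubling the training set does not degrade it by more than 0.01."""
    f = lambda X: (X**2).sum(axis=1)
    test = latin_hypercube(20, UNIT4, seed=11)
    y_test = f(test.values)
    r2 = {}
    for n in (50, 100):
        train = latin_hypercube(n, UNIT4, seed=10)
        model = train_rbnn(train, pd.DataFrame({"y": f(train.values)}))
        r2[n] = fit_metrics(y_test, model.predict(test.values)[:, 0]).r2
    assert r2[50] >= 0.99
    assert r2[100] >= r2[50] - 0.01


def test_rbf_constant_responses_predict_constant():
    design = latin_hypercube(12, UNIT4, seed=4)
    model = train_rbnn(design, pd.DataFrame({"y": np.full(12, 5.0)}))
    probe = np.random.default_rng(0).uniform(0, 1, size=(40, 4))
    assert np.max(np.abs(model.predict(probe)[:, 0] - 5.0)) < 1e-8


def test_rbf_prediction_invariant_to_row_order(pseudo_sim):
    design = latin_hypercube(25, design_domain_box(), seed=6, names=tuple(DESIGN_DOMAIN))
    responses = evaluate_responses(design, pseudo_sim)
    perm = np.random.default_rng(1).permutation(25)
    shuffled = DesignTable(design.names, design.values[perm], design.domain)
    m1 = train_rbnn(design, responses)
    m2 = train_rbnn(shuffled, responses.iloc[perm].reset_index(drop=True))
    probe = latin_hypercube(10, design_domain_box(), seed=9, names=tuple(DESIGN_DOMAIN)).values
    assert np.allclose(m1.predict(probe), m2.predict(probe), atol=1e-7)


def test_rbf_duplicate_points_need_regularization():
    design = latin_hypercube(10, UNIT4, seed=4)
    values = design.values.copy()
    values[1] = values[0]
    dup = DesignTable(design.names, values, design.domain)
    y = pd.DataFrame({"y": np.arange(10.0)})
    with pytest.raises(ValueError, match="duplicate"):
        train_rbnn(dup, y)
    model = train_rbnn(dup, y, regularization=1e-6)  # ridge resolves the tie
    assert np.all(np.isfinite(model.weights))


def test_rbf_json_round_trip(tmp_path, pseudo_sim):
    design = latin_hypercube(20, design_domain_box(), seed=8, names=tuple(DESIGN_DOMAIN))
    model = train_rbnn(design, evaluate_responses(design, pseudo_sim))
    path = tmp_path / "model.json"
    model.save(path)
    clone = SurrogateModel.load(path)
    probe = design.values[:5]
    assert np.allclose(model.predict(probe), clone.predict(probe), atol=0, rtol=0)


def test_rbf_gradient_matches_finite_differences(pseudo_sim):
    design = latin_hypercube(30, design_domain_box(), seed=5, names=tuple(DESIGN_DOMAIN))
    model = train_rbnn(design, evaluate_responses(design, pseudo_sim))
    x = np.array([620.0, 14.0, 31.0, 45.0])
    g = model.gradient(x, "ST")
    f = model.response("ST")
    for i in range(4):
        e = np.zeros(4)
        e[i] = 1e-4 * (1 + abs(x[i]))
        fd = (f(x + e) - f(x - e)) / (2 * e[i])
        assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------

def test_fit_metrics_hand_computed():
    m = fit_metrics(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
    assert m.sse == pytest.approx(1.0)
    assert m.sst == pytest.approx(2.0)
    assert m.r2 == pytest.approx(0.5)
    assert m.rmse == pytest.approx(math.sqrt(1.0 / 3.0))
    assert m.re_min == pytest.approx(-100.0 / 3.0)
    assert m.re_max == pytest.approx(0.0)


def test_fit_metrics_perfect_and_mean_predictor():
    y = np.array([2.0, 4.0, 6.0, 8.0])
    perfect = fit_metrics(y, y)
    assert perfect.sse == 0.0 and perfect.rmse == 0.0 and perfect.r2 == 1.0
    assert (perfect.re_min, perfect.re_max) == (0.0, 0.0)
    mean = fit_metrics(y, np.full_like(y, y.mean()))
    assert mean.r2 == pytest.approx(0.0)


def test_fit_metrics_r2_identity_random():
    rng = np.random.default_rng(3)
    y = rng.normal(size=50)
    y_hat = y + rng.normal(scale=0.3, size=50)
    m = fit_metrics(y, y_hat)
    assert m.r2 == pytest.approx(1.0 - m.sse / m.sst, abs=1e-12)


def test_fit_metrics_edge_cases():
    with pytest.warns(UserWarning, match="zero reference"):
        fit_metrics(np.array([0.0, 1.0, 2.0]), np.array([0.1, 1.0, 2.0]))
    with pytest.warns(UserWarning, match="undefined"):
        m = fit_metrics(np.array([3.0, 3.0]), np.array([3.0, 4.0]))
    assert m.r2 is None
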