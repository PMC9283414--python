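"""Brain-age metrics, LOO offset correction and the GP stand-in."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rapidvol as rv
from rapidvol.brainage import extract_features
from rapidvol.errors import DataError, DegenerateDataError, ParameterError

from conftest import make_mapset


# ---------------------------------------------------------------------------
# MAE and the null benchmark


def test_mae_trivial_cases():
    x = np.array([20.0, 30.0, 40.0])
    assert rv.mae(x, x) == 0.0
    assert rv.mae(x + 5.0, x) == 5.0


def test_mae_matches_sort_oracle():
    rng = np.random.default_rng(101)
    pred = rng.normal(30, 10, 9)
    age = rng.normal(30, 10, 9)
    errors = sorted(abs(p - a) for p, a in zip(pred, age))
    assert rv.mae(pred, age) == pytest.approx(errors[4], abs=1e-12)


@settings(deadline=None, derandomize=True)
@given(st.floats(-30, 30), st.floats(0.1, 5.0))
def test_mae_translation_and_scale(c, a):
    rng = np.random.default_rng(7)
    x = rng.normal(30, 8, 15)
    y = rng.normal(30, 8, 15)
    assert rv.mae(x + c, x) == pytest.approx(abs(c), abs=1e-9)
    assert rv.mae(a * x, a * y) == pytest.approx(a * rv.mae(x, y), rel=1e-9)


def test_null_mae_examples():
    assert rv.null_mae(np.full(5, 40.6)) == 0.0
    assert rv.null_mae(np.array([30.0, 40.0, 50.0])) == pytest.approx(9.4)
    ages = rv.generate_cohort(rv.GeneratorConfig())["age"].to_numpy()
    assert rv.null_mae(ages) == rv.mae(np.full_like(ages, 40.6), ages)


def test_null_mae_ratio_values_and_errors():
    assert rv.null_mae_ratio(10.0, 10.0) == 1.0
    with pytest.raises(ParameterError):
        rv.null_mae_ratio(10.0, 0.0)


def test_model_worse_than_null_gives_ratio_below_one():
    """null_mae_ratio >= 1 is NOT an invariant: an anti-correlated model
    loses to the constant prediction."""
    ages = np.linspace(20, 60, 21)
    adversarial = 80.0 - ages  # predicts old for young and vice versa
    model = rv.mae(adversarial, ages)
    assert rv.null_mae_ratio(rv.null_mae(ages), model) < 1.0


# ---------------------------------------------------------------------------
# LOO offset correction


def test_loo_identity_recovery():
    rng = np.random.default_rng(111)
    age = rng.normal(30, 8, 20)
    pred = age + rng.normal(0, 3, 20)
    adj = rv.loo_adjust(pred, pred, age)
    np.testing.assert_allclose(adj.slopes, 1.0, atol=1e-9)
    np.testing.assert_allclose(adj.intercepts, 0.0, atol=1e-7)
    assert adj.adjusted_mae == pytest.approx(rv.mae(pred, age), abs=1e-9)


def test_loo_constant_offset_removed_exactly():
    rng = np.random.default_rng(112)
    age = rng.normal(30, 8, 20)
    pred_standard = age + rng.normal(0, 3, 20)
    pred_rapid = pred_standard + 12.0
    adj = rv.loo_adjust(pred_rapid, pred_standard, age)
    np.testing.assert_allclose(adj.intercepts, -12.0, atol=1e-7)
    np.testing.assert_allclose(adj.adjusted, pred_standard, atol=1e-8)


def test_loo_folds_match_normal_equations_oracle():
    rng = np.random.default_rng(113)
    age = rng.normal(30, 8, 25)
    pred_standard = age + rng.normal(0, 3, 25)
    pred_rapid = 20.0 + 0.7 * pred_standard + rng.normal(0, 2, 25)
    adj = rv.loo_adjust(pred_rapid, pred_standard, age)
    for i in range(25):
        keep = np.ones(25, bool)
        keep[i] = False
        x, y = pred_rapid[keep], pred_standard[keep]
        m = x.size
        slope = (m * (x * y).sum() - x.sum() * y.sum()) / (
            m * (x * x).sum() - x.sum() ** 2
        )
        intercept = (y.sum() - slope * x.sum()) / m
        assert adj.slopes[i] == pytest.approx(slope, abs=1e-9)
        assert adj.intercepts[i] == pytest.approx(intercept, abs=1e-9)
        assert adj.adjusted[i] == pytest.approx(
            intercept + slope * pred_rapid[i], abs=1e-9
        )


def test_loo_degenerate_predictor_rejected():
    age = np.arange(5.0)
    with pytest.raises(DegenerateDataError):
        rv.loo_adjust(np.full(5, 3.0), age, age)


# ---------------------------------------------------------------------------
# Per-sequence evaluation


def test_evaluate_sequence_perfect_prediction():
    age = np.linspace(20, 50, 10)
    table = pd.DataFrame({"age": age, "pred_standard": age})
    m = rv.evaluate_sequence(table, "standard")
    assert m.rs == 1.0 and m.r2 == pytest.approx(1.0) and m.mae == 0.0
    assert m.null_mae_ratio is None


def test_evaluate_sequence_fields_match_recomputation():
    cfg = rv.GeneratorConfig(seed=2)
    cohort = rv.generate_cohort(cfg)
    preds = rv.generate_age_predictions(cohort, cfg)
    m = rv.evaluate_sequence(preds, "rapid")
    age = preds["age"].to_numpy()
    pred = preds["pred_rapid"].to_numpy()
    rs, p = rv.spearman(age, pred)
    assert (m.rs, m.p) == (rs, p)
    assert m.r2 == rv.pearson_r2(age, pred)
    assert m.mae == rv.mae(pred, age)
    assert m.null_mae == rv.null_mae(age)
    assert m.null_mae_ratio == pytest.approx(m.null_mae / m.mae)


def test_evaluate_sequence_unknown_label():
    table = pd.DataFrame({"age": [1.0, 2.0, 3.0], "pred_standard": [1.0, 2.0, 3.0]})
    with pytest.raises(KeyError):
        rv.evaluate_sequence(table, "nonexistent")


# ---------------------------------------------------------------------------
# GP stand-in


def test_gpr_zero_noise_interpolates_training_points():
    rng = np.random.default_rng(121)
    X = rng.normal(size=(12, 3))
    y = rng.normal(30, 8, 12)
    model = rv.GprAgeModel(noise_variance=0.0, length_scale=1.5).fit(X, y)
    np.testing.assert_allclose(model.predict(X), y, atol=1e-5)


def test_gpr_reverts_to_prior_far_from_data():
    rng = np.random.default_rng(122)
    X = rng.normal(size=(10, 2))
    y = rng.normal(30, 8, 10)
    model = rv.GprAgeModel(length_scale=1.0, noise_variance=1.0).fit(X, y)
    far = np.full((1, 2), 1e4)
    assert model.predict(far)[0] == pytest.approx(model.prior_mean_, abs=1e-6)
    assert model.prior_mean_ == pytest.approx(y.mean())


def test_gpr_three_point_posterior_matches_hand_solve():
    """Posterior mean at one query against an explicit 3x3 linear solve by
    hand-coded Gaussian elimination."""
    X = np.array([[0.0], [1.0], [2.5]])
    y = np.array([25.0, 31.0, 38.0])
    ls, sv, nv = 1.2, 4.0, 0.5
    model = rv.GprAgeModel(
        length_scale=ls, signal_variance=sv, noise_variance=nv, standardize=False
    ).fit(X, y)
    xq = np.array([[1.7]])

    def k(a, b):
        return sv * np.exp(-((a - b) ** 2) / (2 * ls**2))

    # K + nv*I and right-hand side y - mean(y)
    A = np.array([[k(X[i, 0], X[j, 0]) for j in range(3)] for i in range(3)])
    A += nv * np.eye(3)
    b = y - y.mean()
    # Gaussian elimination without pivoting (well conditioned here)
    A = A.astype(float).copy()
    b = b.astype(float).copy()
    for col in range(3):
        for row in range(col + 1, 3):
            f = A[row, col] / A[col, col]
            A[row] -= f * A[col]
            b[row] -= f * b[col]
    alpha = np.zeros(3)
    for row in (2, 1, 0):
        alpha[row] = (b[row] - A[row, row + 1 :] @ alpha[row + 1 :]) / A[row, row]
    expected = y.mean() + sum(k(xq[0, 0], X[i, 0]) * alpha[i] for i in range(3))
    assert model.predict(xq)[0] == pytest.approx(expected, abs=1e-8)


def test_gpr_posterior_mean_linear_in_targets():
    rng = np.random.default_rng(123)
    X = rng.normal(size=(8, 2))
    y1 = rng.normal(30, 5, 8)
    y2 = rng.normal(30, 5, 8)
    kwargs = dict(length_scale=2.0, signal_variance=3.0, noise_variance=0.3,
                  prior_mean=0.0, standardize=False)
    xq = rng.normal(size=(4, 2))
    p1 = rv.GprAgeModel(**kwargs).fit(X, y1).predict(xq)
    p2 = rv.GprAgeModel(**kwargs).fit(X, y2).predict(xq)
    p12 = rv.GprAgeModel(**kwargs).fit(X, 0.3 * y1 + 0.7 * y2).predict(xq)
    np.testing.assert_allclose(p12, 0.3 * p1 + 0.7 * p2, atol=1e-8)


def test_gpr_functional_wrappers_and_validation():
    X = np.arange(6, dtype=float).reshape(-1, 1)
    y = np.arange(6, dtype=float)
    model = rv.gpr_fit(X, y, length_scale=2.0)
    np.testing.assert_allclose(rv.gpr_predict(model, X), model.predict(X))
    with pytest.raises(DataError):
        rv.gpr_fit(X[:1], y[:1])


# ---------------------------------------------------------------------------
# Features and the FoV offset experiment


def test_extract_features_octants_sum_to_total():
    cfg = rv.GeneratorConfig(n_participants=6, n_retest=0, seed=9)
    cohort = rv.generate_cohort(cfg)
    maps = rv.generate_tissue_maps(cohort, cfg)["standard"]
    X, names = extract_features(maps)
    assert X.shape == (6, 11)
    assert names[:3] == ["total_GM", "total_WM", "total_CSF"]
    np.testing.assert_allclose(X[:, 3:].sum(axis=1), X[:, 0], rtol=1e-12)


def test_fov_experiment_zero_truncation_identical():
    cfg = rv.GeneratorConfig(n_participants=24, n_retest=0, fov_drop_slices=0, seed=3)
    rep = rv.fov_offset_experiment(cfg, n_train=40)
    assert rep.mae_truncated == pytest.approx(rep.mae_full, abs=1e-9)
    assert rep.rs_truncated == pytest.approx(rep.rs_full, abs=1e-9)


def test_fov_experiment_deterministic():
    cfg = rv.GeneratorConfig(n_participants=24, n_retest=0, seed=4)
    r1 = rv.fov_offset_experiment(cfg, n_train=40)
    r2 = rv.fov_offset_experiment(cfg, n_train=40)
    assert r1.to_dict() == r2.to_dict()
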