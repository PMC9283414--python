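"""Association and reliability statistics against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rapidvol import (
    bootstrap_corr_difference,
    icc_3_1,
    icc_map,
    pearson_r2,
    spearman,
)
from rapidvol.errors import DataError, DegenerateDataError, ParameterError

from conftest import make_mapset


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_monotone_limits():
    x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
    rs, p = spearman(x, np.exp(x / 3.0))
    assert rs == 1.0 and p == 0.0
    rs, _ = spearman(x, x[::-1])
    assert rs == -1.0


def test_spearman_matches_d_squared_formula():
    """No ties: rs = 1 - 6*sum(d^2) / (n(n^2-1)) on a 5-point example."""
    x = np.array([1, 2, 3, 4, 5], dtype=float)
    y = np.array([2, 1, 4, 3, 5], dtype=float)
    d = x - y  # ranks equal values here
    n = 5
    expected = 1.0 - 6.0 * (d**2).sum() / (n * (n**2 - 1))
    rs, p = spearman(x, y)
    assert rs == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.8)
    assert 0.0 <= p <= 1.0


@settings(deadline=None, derandomize=True)
@given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=20, unique=True),
       st.integers(0, 2**31 - 1))
def test_spearman_monotone_invariance_and_reversal(xs, seed):
    x = np.array(xs, dtype=float)
    y = np.random.default_rng(seed).permutation(len(x)).astype(float)
    rs, _ = spearman(x, y)
    rs_t, _ = spearman(np.exp(x / 1200.0), y)  # strictly monotone transform
    assert rs_t == pytest.approx(rs, abs=1e-9)
    rs_rev, _ = spearman(-x, y)  # order reversal flips the sign
    assert rs_rev == pytest.approx(-rs, abs=1e-9)


def test_spearman_validation():
    with pytest.raises(DegenerateDataError):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(DataError):
        spearman([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(DataError):
        spearman([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Pearson r^2


def test_r2_perfect_linear_and_hand_example():
    x = np.arange(7.0)
    assert pearson_r2(x, 2 * x + 1) == pytest.approx(1.0)

    y = np.array([2.0, 1.0, 4.0, 3.0, 7.0, 5.0, 8.0])
    # covariance-formula oracle computed by explicit sums
    xc, yc = x - x.mean(), y - y.mean()
    r_oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    assert pearson_r2(x, y) == pytest.approx(r_oracle**2, abs=1e-12)


def test_r2_independent_noise_near_zero():
    rng = np.random.default_rng(61)
    assert pearson_r2(rng.normal(size=10_000), rng.normal(size=10_000)) < 0.01


# ---------------------------------------------------------------------------
# Bootstrap difference in association strength


def test_bootstrap_identical_contrasts_degenerate_at_zero():
    rng = np.random.default_rng(71)
    age = rng.normal(30, 8, 40)
    v = 0.5 * age + rng.normal(0, 3, 40)
    res = bootstrap_corr_difference(
        age, {"a": v, "b": v.copy()}, statistic="rs", n_boot=200, seed=1
    )[("a", "b")]
    assert res.ci_low == res.ci_high == res.median == 0.0
    assert res.ci_includes_zero


def test_bootstrap_seed_determinism_and_validation():
    rng = np.random.default_rng(72)
    age = rng.normal(30, 8, 30)
    contrasts = {
        "a": 0.4 * age + rng.normal(0, 4, 30),
        "b": 0.2 * age + rng.normal(0, 4, 30),
    }
    r1 = bootstrap_corr_difference(age, contrasts, n_boot=300, seed=9)[("a", "b")]
    r2 = bootstrap_corr_difference(age, contrasts, n_boot=300, seed=9)[("a", "b")]
    assert (r1.ci_low, r1.median, r1.ci_high) == (r2.ci_low, r2.median, r2.ci_high)
    assert r1.ci_low <= r1.median <= r1.ci_high
    with pytest.raises(ParameterError):
        bootstrap_corr_difference(age, contrasts, n_boot=0)
    with pytest.raises(ParameterError):
        bootstrap_corr_difference(age, contrasts, statistic="tau")


def test_bootstrap_detects_a_real_difference():
    rng = np.random.default_rng(73)
    age = rng.normal(30, 8, 200)
    strong = 0.9 * age + rng.normal(0, 1, 200)
    weak = 0.05 * age + rng.normal(0, 8, 200)
    res = bootstrap_corr_difference(
        age, {"strong": strong, "weak": weak}, n_boot=1000, seed=2
    )[("strong", "weak")]
    assert res.ci_low > 0.0 and not res.ci_includes_zero


# ---------------------------------------------------------------------------
# ICC


def _icc3_loop_oracle(x):
    """Brute-force two-way ANOVA decomposition with explicit loops."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ss_sub = k * sum((r - grand) ** 2 for r in row)
    ss_rat = n * sum((c - grand) ** 2 for c in col)
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_sub = ss_sub / (n - 1)
    ms_err = (ss_tot - ss_sub - ss_rat) / ((n - 1) * (k - 1))
    return (ms_sub - ms_err) / (ms_sub + (k - 1) * ms_err)


def test_icc_matches_loop_anova_oracle():
    rng = np.random.default_rng(81)
    for _ in range(50):
        table = rng.normal(10, 2, size=(6, 2))
        assert icc_3_1(table).icc == pytest.approx(
            _icc3_loop_oracle(table), abs=1e-10
        )


def test_icc_perfect_and_shift_invariant():
    rng = np.random.default_rng(82)
    a = rng.normal(100, 10, 8)
    assert icc_3_1(np.column_stack([a, a])).icc == pytest.approx(1.0)
    res = icc_3_1(np.column_stack([a, a + 7.5]))
    assert res.icc == pytest.approx(1.0, abs=1e-12)


def test_icc_matches_pingouin():
    """Independent cross-check of point estimate and CI against pingouin."""
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(83)
    table = rng.normal(50, 5, size=(12, 2)) + rng.normal(0, 3, size=(12, 1))
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["t", "r"], 12),
            "score": table.ravel(),
        }
    )
    pg = pingouin.intraclass_corr(
        long, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    ci_col = "CI95" if "CI95" in pg.columns else "CI95%"
    ours = icc_3_1(table, form="icc3")
    assert ours.icc == pytest.approx(pg.loc["ICC(C,1)", "ICC"], abs=1e-9)
    np.testing.assert_allclose(
        ours.ci95, np.asarray(pg.loc["ICC(C,1)", ci_col], dtype=float), atol=6e-3
    )
    ours1 = icc_3_1(table, form="icc1")
    assert ours1.icc == pytest.approx(pg.loc["ICC(1,1)", "ICC"], abs=1e-9)


def test_icc_variance_ratio_recovery():
    """On simulated two-way data the ICC recovers
    var_subject / (var_subject + var_noise)."""
    rng = np.random.default_rng(84)
    n = 500
    subj = rng.normal(0, 3, n)
    table = subj[:, None] + rng.normal(0, 1.5, size=(n, 2))
    expected = 9.0 / (9.0 + 2.25)
    res = icc_3_1(table)
    assert res.icc == pytest.approx(expected, abs=0.02)
    assert res.ci95[0] <= res.icc <= res.ci95[1]
    assert res.icc <= 1.0
    assert 0.0 <= res.p <= 1.0


def test_icc_validation():
    with pytest.raises(DegenerateDataError):
        icc_3_1(np.full((5, 2), 3.0))
    with pytest.raises(DataError):
        icc_3_1(np.ones((1, 2)))
    with pytest.raises(DataError):
        icc_3_1(np.array([[1.0, np.nan], [2.0, 3.0]]))


# ---------------------------------------------------------------------------
# Voxel-wise ICC


def test_icc_map_perfect_retest_is_one():
    rng = np.random.default_rng(91)
    vals = rng.uniform(1, 5, size=(6, 3, 3, 2))
    a = make_mapset(vals, sequence="rapid")
    b = make_mapset(vals.copy(), sequence="retest")
    out = icc_map(a, b, np.ones((3, 3, 2), bool))
    np.testing.assert_allclose(out, 1.0, atol=1e-10)


def test_icc_map_matches_scalar_per_voxel():
    rng = np.random.default_rng(92)
    a = make_mapset(rng.uniform(1, 5, size=(8, 2, 2, 3)))
    b = make_mapset(rng.uniform(1, 5, size=(8, 2, 2, 3)))
    out = icc_map(a, b, np.ones((2, 2, 3), bool))
    for idx in np.ndindex(2, 2, 3):
        table = np.column_stack(
            [a.values[(slice(None),) + idx], b.values[(slice(None),) + idx]]
        )
        assert out[idx] == pytest.approx(icc_3_1(table).icc, abs=1e-10)


def test_icc_map_degenerate_voxels_counted_by_brute_force():
    rng = np.random.default_rng(93)
    a_vals = rng.uniform(1, 5, size=(5, 2, 2, 2))
    b_vals = rng.uniform(1, 5, size=(5, 2, 2, 2))
    a_vals[:, 0, 0, 0] = b_vals[:, 0, 0, 0] = 2.0  # fully constant table
    a_vals[:, 1, 1, 1] = b_vals[:, 1, 1, 1] = 3.0
    out = icc_map(make_mapset(a_vals), make_mapset(b_vals), np.ones((2, 2, 2), bool))
    degenerate = 0
    for idx in np.ndindex(2, 2, 2):
        table = np.column_stack(
            [a_vals[(slice(None),) + idx], b_vals[(slice(None),) + idx]]
        )
        if np.ptp(table) == 0:
            degenerate += 1
    assert np.isnan(out).sum() == degenerate == 2
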