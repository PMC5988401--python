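"""Robust quantile statistics, shift function, KS, Holm, group tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from muxvis import (bayes_boot_hdi, flag_outliers, group_covariate_test,
                    harrell_davis, hd_weights, holm_adjust, ks_critical,
                    ks_statistic, shift_function)

samples = st.lists(st.floats(-100, 100, allow_nan=False,
                             allow_infinity=False), min_size=2, max_size=30)


@pytest.mark.parametrize("x,q,expected", [
    ([1, 2, 3], 0.5, 2.0),
    ([5, 5, 5, 5], 0.3, 5.0),
    ([5, 5, 5, 5], 0.8, 5.0),
    ([1, 2, 3, 4], 0.5, 2.5),
])
def test_harrell_davis_worked_examples(x, q, expected):
    assert harrell_davis(x, q) == pytest.approx(expected, abs=1e-12)


def test_harrell_davis_median_independent_beta_formula(rng):
    # independent evaluation of the Beta-weight formula
    x = np.sort(rng.standard_normal(17))
    n, q = x.size, 0.37
    a, b = (n + 1) * q, (n + 1) * (1 - q)
    w = np.array([special.betainc(a, b, (i + 1) / n)
                  - special.betainc(a, b, i / n) for i in range(n)])
    assert harrell_davis(x, q) == pytest.approx(float(w @ x), abs=1e-12)


@given(samples, st.floats(0.01, 0.99))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_hd_weights_sum_and_location_scale_equivariance(x, q):
    x = np.asarray(x)
    assert hd_weights(len(x), q).sum() == pytest.approx(1.0, abs=1e-12)
    est = harrell_davis(x, q)
    assert harrell_davis(3.0 * x + 7.0, q) == pytest.approx(
        3.0 * est + 7.0, abs=1e-8 * (1 + abs(est)))


def test_hd_monotone_in_q(rng):
    x = rng.standard_normal(25)
    qs = np.linspace(0.05, 0.95, 19)
    est = [harrell_davis(x, q) for q in qs]
    assert np.all(np.diff(est) >= -1e-12)
    with pytest.raises(ValueError):
        harrell_davis(x, 0.0)


def test_bayes_boot_constant_sample_and_determinism(rng):
    pt, (lo, hi) = bayes_boot_hdi([5.0] * 10, n_draws=300, seed=1)
    assert pt == pytest.approx(5.0)
    assert hi - lo == pytest.approx(0.0, abs=1e-12)
    x = rng.standard_normal(50)
    assert bayes_boot_hdi(x, seed=42, n_draws=300) == bayes_boot_hdi(
        x, seed=42, n_draws=300)
    with pytest.warns(UserWarning):
        bayes_boot_hdi(x, n_draws=50, seed=0)
    with pytest.raises(ValueError):
        bayes_boot_hdi(x, level=1.5)


def test_bayes_boot_hdi_coverage(rng):
    """95% HDIs for the median of N(0,1) samples cover 0 >= 93% of the time."""
    cover = 0
    n_sim = 200
    for _ in range(n_sim):
        x = rng.standard_normal(200)
        _, (lo, hi) = bayes_boot_hdi(x, n_draws=400,
                                     seed=int(rng.integers(2**31)))
        cover += lo <= 0.0 <= hi
    assert cover / n_sim >= 0.93


def test_shift_function_identical_samples_all_zero(rng):
    x = rng.standard_normal(40)
    sf = shift_function(x, x, n_boot=200, seed=0)
    assert np.all(sf.differences == 0.0)
    assert np.all(sf.lower <= sf.differences)
    assert np.all(sf.upper >= sf.differences)


def test_shift_function_pure_location_shift(rng):
    x = rng.standard_normal(60)
    sf = shift_function(x, x + 1.0, n_boot=200, seed=3)
    assert np.allclose(sf.differences, -1.0, atol=1e-10)
    frame = sf.to_frame()
    assert list(frame.columns) == ["quantile", "decile_x", "decile_y",
                                   "difference", "lower", "upper"]
    with pytest.raises(ValueError):
        shift_function(x[:5], x, n_boot=100)


def test_ks_statistic_examples(rng):
    x = rng.standard_normal(30)
    assert ks_statistic(x, x) == 0.0
    assert ks_statistic([1, 2, 3], [10, 11]) == 1.0  # disjoint supports
    assert ks_statistic([1, 3], [2, 4]) == pytest.approx(0.5)
    # invariance under a common strictly increasing transform
    y = rng.standard_normal(25)
    assert ks_statistic(np.exp(x), np.exp(y)) == pytest.approx(
        ks_statistic(x, y), abs=1e-15)


def test_ks_critical_closed_form_and_monotonicity():
    assert ks_critical(0.05, 40, 40) == pytest.approx(
        1.3581015157406195 * np.sqrt(2 / 40), rel=1e-4)
    assert ks_critical(0.001, 10, 12) > ks_critical(0.01, 10, 12)
    with pytest.raises(ValueError):
        ks_critical(0.0, 10, 10)


def test_holm_adjustment():
    assert holm_adjust([0.2]).tolist() == [0.2]
    assert np.allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])
    p = np.array([0.5, 0.6, 0.9])
    adj = holm_adjust(p)
    assert np.all(adj >= p) and np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= 0)
    with pytest.raises(ValueError):
        holm_adjust([1.5])


def test_group_covariate_test_type_one_error(rng):
    """Rejection rate under a permuted-null design stays near alpha."""
    rej = 0
    n_sim = 500
    for _ in range(n_sim):
        vals = rng.standard_normal(60)
        groups = rng.permutation(np.repeat(["a", "b"], 30))
        covs = rng.standard_normal((60, 2))
        rej += group_covariate_test(vals, groups, covs) < 0.05
    assert abs(rej / n_sim - 0.05) <= 0.02 + 1e-12  # guard float round-off


def test_group_covariate_test_power_and_errors(rng):
    groups = np.repeat(["a", "b"], 30)
    vals = rng.standard_normal(60) * 0.1 + (groups == "b") * 5.0
    covs = rng.standard_normal((60, 2))
    assert group_covariate_test(vals, groups, covs) < 1e-3
    with pytest.raises(ValueError, match="rank-deficient"):
        group_covariate_test(vals, groups,
                             (groups == "b").astype(float)[:, None])
    with pytest.raises(ValueError, match="2 groups"):
        group_covariate_test(vals, np.repeat("a", 60), covs)


def test_group_covariate_test_multivariate_pillai(rng):
    groups = np.repeat(["a", "b", "c"], 25)
    resp = rng.standard_normal((75, 4))
    resp[groups == "b"] += 1.5
    p = group_covariate_test(resp, groups, rng.standard_normal((75, 2)),
                             multivariate=True)
    assert p < 1e-4
    p_null = group_covariate_test(rng.standard_normal((75, 4)), groups,
                                  multivariate=True)
    assert 0.0 < p_null <= 1.0


def test_flag_outliers_rules():
    assert not flag_outliers([3.0, 3.0, 3.0, 3.0]).any()
    flags = flag_outliers([0.0, 0.1, 0.2, 0.15, 100.0])
    assert flags.tolist() == [False, False, False, False, True]
    # affine invariance of the ratio-based rule
    x = np.array([0.0, 0.1, 0.2, 0.15, 100.0])
    assert np.array_equal(flag_outliers(-3.0 * x + 2.0), flags)
    assert flag_outliers(x, method="mad")[-1]
    with pytest.raises(ValueError):
        flag_outliers([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        flag_outliers(x, method="nope")
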