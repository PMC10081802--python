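"""Core MW effect-size and Wei-Lachin pooling statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

import tbisens as tb
from tbisens.mwstats import InfeasibleComparison, inverse_variance_weights


def brute_theta(x, y):
    """Independent double-loop oracle (kept separate from the package's own
    brute-force path)."""
    wins = ties = 0
    for xi in x:
        for yj in y:
            wins += xi > yj
            ties += xi == yj
    return (wins + 0.5 * ties) / (len(x) * len(y))


def test_midrank_equals_bruteforce_on_random_tied_instances(rng):
    for _ in range(200):
        n1, n2 = rng.integers(1, 31, size=2)
        # few distinct levels -> heavy ties
        x = rng.integers(0, 5, n1).astype(float)
        y = rng.integers(0, 5, n2).astype(float)
        est = tb.mw_effect(x, y)
        expected = brute_theta(x, y)
        assert abs(est.theta - expected) <= 1e-12
        assert abs(tb.mw_effect_bruteforce(x, y) - expected) <= 1e-12


def test_theta_equals_roc_auc(rng):
    x = rng.normal(1, 1, 80)
    y = np.round(rng.normal(0, 1, 60), 1)  # some ties after rounding
    est = tb.mw_effect(x, y)
    auc = roc_auc_score(np.r_[np.ones(80), np.zeros(60)], np.r_[x, y])
    assert est.theta == pytest.approx(auc, abs=1e-12)


@pytest.mark.parametrize("x,y,expected", [
    ([1, 2, 3], [1, 2, 3], 0.5),
    ([4, 5, 6], [1, 2, 3], 1.0),
    ([1, 2], [2, 3], 0.125),  # 0 wins + 1 tie of the 4 cross-pairs
])
def test_known_effect_sizes(x, y, expected):
    assert tb.mw_effect(x, y).theta == expected


@given(st.lists(st.integers(0, 6), min_size=1, max_size=25),
       st.lists(st.integers(0, 6), min_size=1, max_size=25))
def test_antisymmetry_is_exact_under_ties(xs, ys):
    assert tb.mw_effect(xs, ys).theta + tb.mw_effect(ys, xs).theta == 1.0


@given(st.lists(st.integers(-20, 20), min_size=2, max_size=25),
       st.lists(st.integers(-20, 20), min_size=2, max_size=25))
def test_rank_invariance_under_monotone_transforms(xs, ys):
    base = tb.mw_effect(xs, ys).theta
    for f in (lambda v: np.exp(np.asarray(v, float) / 10),
              lambda v: np.asarray(v, float) ** 3,
              lambda v: 5 * np.asarray(v, float) - 7):
        assert tb.mw_effect(f(xs), f(ys)).theta == pytest.approx(base, abs=1e-12)


def test_empty_arm_is_infeasible():
    with pytest.raises(InfeasibleComparison):
        tb.mw_effect([], [1, 2])
    with pytest.raises(InfeasibleComparison):
        tb.mw_effect([np.nan, np.nan], [1, 2])


# --- variance ----------------------------------------------------------------

def jackknife_se(x, y):
    """Grouped delete-one jackknife oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    t1 = [tb.mw_effect(np.delete(x, i), y).theta for i in range(n1)]
    t2 = [tb.mw_effect(x, np.delete(y, j)).theta for j in range(n2)]
    v1 = (n1 - 1) / n1 * np.sum((np.asarray(t1) - np.mean(t1)) ** 2)
    v2 = (n2 - 1) / n2 * np.sum((np.asarray(t2) - np.mean(t2)) ** 2)
    return math.sqrt(v1 + v2)


def test_se_matches_jackknife_exactly(rng):
    cases = [([1, 2], [2, 3])]
    for _ in range(10):
        cases.append((rng.integers(0, 6, rng.integers(3, 15)),
                      rng.integers(0, 6, rng.integers(3, 15))))
    for x, y in cases:
        se, _ = tb.mw_se(x, y)
        assert se == pytest.approx(jackknife_se(x, y), abs=1e-12)


def test_se_null_matches_asymptotic_value(rng):
    # same continuous distribution: var ~ 1/12 (1/n1 + 1/n2)
    n1 = n2 = 400
    x, y = rng.normal(size=n1), rng.normal(size=n2)
    se, degenerate = tb.mw_se(x, y)
    expected = math.sqrt((1 / n1 + 1 / n2) / 12)
    assert not degenerate
    assert se == pytest.approx(expected, rel=0.15)


def test_se_degenerate_under_complete_separation():
    se, degenerate = tb.mw_se([10, 11], [1, 2])
    assert se == 0.0 and degenerate
    se, degenerate = tb.mw_se([1], [1, 2])
    assert math.isnan(se) and degenerate


# --- confidence intervals ----------------------------------------------------

def test_wald_interval_and_clipping():
    lo, hi = tb.mw_ci(0.5, 0.05)
    assert (round(lo, 3), round(hi, 3)) == (0.402, 0.598)
    assert tb.mw_ci(0.99, 0.05)[1] == 1.0
    assert tb.mw_ci(0.4, 0.05, level=0.0) == (0.4, 0.4)
    assert tb.mw_ci(0.4, 0.0) == (0.4, 0.4)


def test_logit_interval_stays_inside_unit_interval():
    lo, hi = tb.mw_ci(0.97, 0.05, scale="logit")
    assert 0.0 < lo < 0.97 < hi < 1.0


# --- covariance & pooling ----------------------------------------------------

def test_cov_duplicated_outcome_has_unit_correlation(rng):
    x = rng.normal(size=(40, 1))
    y = rng.normal(0.3, 1, size=(35, 1))
    thetas, sigma = tb.mw_cov(np.hstack([x, x]), np.hstack([y, y]))
    assert thetas[0] == thetas[1]
    assert sigma[0, 1] == pytest.approx(sigma[0, 0], abs=1e-12)


def test_cov_diagonal_equals_univariate_variance(rng):
    a1 = rng.normal(size=(30, 3)).round(1)
    a2 = rng.normal(size=(25, 3)).round(1)
    thetas, sigma = tb.mw_cov(a1, a2)
    for k in range(3):
        se, _ = tb.mw_se(a1[:, k], a2[:, k])
        assert sigma[k, k] == pytest.approx(se ** 2, abs=1e-12)
        assert thetas[k] == pytest.approx(tb.mw_effect(a1[:, k], a2[:, k]).theta)


def test_cov_independent_outcomes_nearly_uncorrelated(rng):
    a1 = rng.normal(size=(2000, 2))
    a2 = rng.normal(size=(2000, 2))
    _, sigma = tb.mw_cov(a1, a2)
    r = sigma[0, 1] / math.sqrt(sigma[0, 0] * sigma[1, 1])
    assert abs(r) < 0.1


def test_cov_single_outcome_and_infeasibility(rng):
    a1, a2 = rng.normal(size=(10, 1)), rng.normal(size=(12, 1))
    _, sigma = tb.mw_cov(a1, a2)
    assert sigma.shape == (1, 1)
    with pytest.raises(InfeasibleComparison):
        tb.mw_cov(np.full((5, 2), np.nan), a2[:, [0, 0]])


def test_pooling_identities(rng):
    assert tb.pool_mmw([0.3, 0.5], np.eye(2) * 1e-3).pooled_theta == pytest.approx(0.4)
    null = tb.pool_mmw([0.5, 0.5, 0.5], np.eye(3) * 1e-3)
    assert null.z == 0.0 and null.p == 1.0
    thetas = rng.uniform(0.2, 0.8, 6)
    a = rng.normal(size=(6, 6))
    sigma = a @ a.T / 100
    pooled = tb.pool_mmw(thetas, sigma)
    assert pooled.pooled_theta == pytest.approx(thetas.mean(), abs=1e-12)


def test_pooled_variance_never_exceeds_worst_outcome(rng):
    for _ in range(20):
        a = rng.normal(size=(4, 4))
        sigma = a @ a.T / 50
        d = np.sqrt(np.diag(sigma))
        corr_ok = np.all(np.abs(sigma / np.outer(d, d)) <= 1 + 1e-12)
        pooled = tb.pool_mmw(rng.uniform(0, 1, 4), sigma)
        if corr_ok:
            assert pooled.pooled_se ** 2 <= max(np.diag(sigma)) + 1e-12


def test_pool_input_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        tb.pool_mmw([0.4, 0.6], np.eye(2), weights=[0.7, 0.7])
    degenerate = tb.pool_mmw([0.4, 0.6], np.zeros((2, 2)))
    assert degenerate.degenerate and math.isnan(degenerate.p)


def test_inverse_variance_weights_favor_precise_outcomes():
    w = inverse_variance_weights(np.diag([1.0, 0.25]))
    assert w == pytest.approx([0.2, 0.8])


# --- classification & multiplicity -------------------------------------------

@pytest.mark.parametrize("theta,expected", [
    (0.0, "large"), (0.29, "large"), (0.71, "large"), (1.0, "large"),
    (0.295, "medium"), (0.35, "medium"), (0.65, "medium"), (0.67, "medium"),
    (0.36, "small"), (0.5, "small"), (0.64, "small"),
])
def test_effect_class_boundary_membership(theta, expected):
    assert tb.classify_effect(theta) == expected


def test_effect_class_rejects_out_of_range():
    with pytest.raises(ValueError):
        tb.classify_effect(1.2)


def test_adjusted_alphas():
    assert tb.adjust_alpha("design_A_instruments") == 0.00045
    assert tb.adjust_alpha("design_A_groups") == 0.0001
    assert tb.adjust_alpha("design_B_proms") == 0.005
    assert tb.adjust_alpha("generic", m=10) == pytest.approx(0.005)
    with pytest.raises(KeyError):
        tb.adjust_alpha("nonexistent_family")
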