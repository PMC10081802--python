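"""Mann-Whitney effect sizes and the Wei-Lachin multivariate rank procedure.

The Mann-Whitney (MW) effect size for two arms X and Y is

    theta = P(X > Y) + 0.5 * P(X = Y),

the probability that a randomly chosen member of the first arm has the
better (oriented) outcome, with ties weighted one half. It equals the area
under the ROC curve; 0.5 means stochastic equality. The estimator here uses
midranks (O(n log n)); a brute-force pair-counting path is kept for
cross-checking.

Standard errors come from the two-sample U-statistic component (placement
value) estimator: with placements V10_i = P_hat(x_i > Y) and
V01_j = P_hat(X > y_j),

    var(theta_hat) = S10 / n1 + S01 / n2,

where S10, S01 are the sample variances of the placements. This is the
DeLong estimator for the AUC, consistent under ties, and algebraically
identical to the grouped delete-one jackknife. The same placements give the
covariance between MW estimates of different outcomes measured on the same
subjects, which is what the Wei-Lachin procedure pools: a weighted
combination w'theta with variance w'Sigma w tested against 0.5.

Effect-size bands follow the convention small for 0.36 <= theta <= 0.64,
large for theta <= 0.29 or theta >= 0.71, medium in between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MWEstimate",
    "PooledMWResult",
    "InfeasibleComparison",
    "mw_effect",
    "mw_effect_bruteforce",
    "mw_se",
    "mw_ci",
    "mw_cov",
    "pool_mmw",
    "classify_effect",
    "adjust_alpha",
    "bonferroni",
    "EFFECT_BOUNDS",
    "ALPHA_FAMILIES",
]

#: (large_low, small_low, small_high, large_high); boundary membership:
#: 0.36 and 0.64 belong to small, 0.29 and 0.71 to large.
EFFECT_BOUNDS = (0.29, 0.36, 0.64, 0.71)

#: Bonferroni-adjusted significance levels per analysis family.
ALPHA_FAMILIES: dict[str, float] = {
    "design_A_instruments": 0.00045,
    "design_A_groups": 0.0001,
    "design_B_proms": 0.005,
    "design_B_groups": 0.0001,
}


class InfeasibleComparison(ValueError):
    """Raised when a comparison cannot be computed (e.g. an empty arm)."""


@dataclass(frozen=True)
class MWEstimate:
    """Tie-corrected MW effect size for one two-arm comparison."""

    theta: float
    se: float
    ci: tuple[float, float]
    n1: int
    n2: int
    n_ties: int           # tied cross-arm pairs
    degenerate: bool = False  # zero placement variability (e.g. separation)

    @property
    def z(self) -> float:
        if self.se <= 0:
            return float("nan")
        return (self.theta - 0.5) / self.se

    @property
    def p(self) -> float:
        z = self.z
        return float("nan") if math.isnan(z) else 2.0 * stats.norm.sf(abs(z))


@dataclass(frozen=True)
class PooledMWResult:
    """Wei-Lachin pooled MW estimate over K correlated outcomes."""

    thetas: np.ndarray
    covariance: np.ndarray
    weights: np.ndarray
    pooled_theta: float
    pooled_se: float
    pooled_ci: tuple[float, float]
    z: float
    p: float
    degenerate: bool = False


def _clean(a) -> np.ndarray:
    a = np.asarray(a, dtype=float).ravel()
    return a[~np.isnan(a)]


def _placements(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """V10_i = (#{y < x_i} + 0.5 #{y = x_i}) / n2 for each x_i."""
    ys = np.sort(y)
    left = np.searchsorted(ys, x, side="left")
    right = np.searchsorted(ys, x, side="right")
    return (left + 0.5 * (right - left)) / len(y)


def _count_ties(x: np.ndarray, y: np.ndarray) -> int:
    ys = np.sort(y)
    left = np.searchsorted(ys, x, side="left")
    right = np.searchsorted(ys, x, side="right")
    return int((right - left).sum())


def mw_effect(x, y, ci_level: float = 0.95, ci_scale: str = "identity") -> MWEstimate:
    """Tie-corrected MW effect size with placement-value SE and CI.

    Missing values are dropped per arm. Raises :class:`InfeasibleComparison`
    when either arm is empty after dropping. The SE requires at least two
    observations per arm and is NaN otherwise.
    """
    x, y = _clean(x), _clean(y)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise InfeasibleComparison("empty arm after dropping missing values")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    theta = u / (n1 * n2)
    n_ties = _count_ties(x, y)
    se, degenerate = mw_se(x, y)
    ci = mw_ci(theta, se, ci_level, scale=ci_scale)
    return MWEstimate(float(theta), se, ci, n1, n2, n_ties, degenerate)


def mw_effect_bruteforce(x, y) -> float:
    """O(n1*n2) pair-counting reference for the midrank estimator."""
    x, y = _clean(x), _clean(y)
    if len(x) == 0 or len(y) == 0:
        raise InfeasibleComparison("empty arm")
    wins = sum(1.0 for xi in x for yj in y if xi > yj)
    ties = sum(1.0 for xi in x for yj in y if xi == yj)
    return (wins + 0.5 * ties) / (len(x) * len(y))


def mw_se(x, y) -> tuple[float, bool]:
    """Placement-value (DeLong) standard error; (NaN, True) when either arm
    has fewer than two observations; (0, True) under complete degeneracy."""
    x, y = _clean(x), _clean(y)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        return float("nan"), True
    v10 = _placements(x, y)           # P_hat(x_i beats Y)
    v01 = 1.0 - _placements(y, x)     # P_hat(X beats y_j)
    var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n2
    se = math.sqrt(max(var, 0.0))
    return se, se == 0.0


def mw_ci(theta: float, se: float, level: float = 0.95,
          scale: str = "identity") -> tuple[float, float]:
    """Wald CI for theta, clipped to [0, 1]; optional logit scale.

    A degenerate (zero or NaN) SE collapses the interval to the point
    estimate; ``level=0`` gives a zero-width interval by construction.
    """
    if not 0.0 <= level < 1.0:
        raise ValueError("confidence level must be in [0, 1)")
    if math.isnan(se) or se == 0.0:
        return (theta, theta)
    zq = stats.norm.ppf(0.5 + level / 2.0)
    if scale == "identity":
        lo, hi = theta - zq * se, theta + zq * se
        return (max(lo, 0.0), min(hi, 1.0))
    if scale == "logit":
        eps = 1e-12
        t = min(max(theta, eps), 1 - eps)
        lt = math.log(t / (1 - t))
        se_l = se / (t * (1 - t))
        lo, hi = lt - zq * se_l, lt + zq * se_l
        return (1 / (1 + math.exp(-lo)), 1 / (1 + math.exp(-hi)))
    raise ValueError(f"unknown CI scale {scale!r}")


def mw_cov(arm1: np.ndarray, arm2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-outcome MW estimates and their covariance for K outcomes.

    ``arm1``/``arm2`` are (subjects x K) matrices of oriented scores with
    complete cases only (rows with any NaN are dropped). Returns
    ``(thetas, Sigma)`` where ``Sigma[k, l]`` estimates the covariance
    between the MW estimates of outcomes k and l, built from cross-outcome
    products of centered placement values; the diagonal equals ``mw_se**2``.
    """
    arm1 = np.asarray(arm1, dtype=float)
    arm2 = np.asarray(arm2, dtype=float)
    if arm1.ndim != 2 or arm2.ndim != 2 or arm1.shape[1] != arm2.shape[1]:
        raise ValueError("arms must be (subjects x K) with matching K")
    arm1 = arm1[~np.isnan(arm1).any(axis=1)]
    arm2 = arm2[~np.isnan(arm2).any(axis=1)]
    n1, n2 = len(arm1), len(arm2)
    if n1 < 2 or n2 < 2:
        raise InfeasibleComparison("fewer than 2 complete-case subjects per arm")
    K = arm1.shape[1]
    v10 = np.empty((n1, K))
    v01 = np.empty((n2, K))
    thetas = np.empty(K)
    for k in range(K):
        v10[:, k] = _placements(arm1[:, k], arm2[:, k])
        v01[:, k] = 1.0 - _placements(arm2[:, k], arm1[:, k])
        thetas[k] = v10[:, k].mean()
    s10 = np.cov(v10, rowvar=False, ddof=1).reshape(K, K)
    s01 = np.cov(v01, rowvar=False, ddof=1).reshape(K, K)
    sigma = s10 / n1 + s01 / n2
    return thetas, sigma


def pool_mmw(thetas, covariance, weights=None, ci_level: float = 0.95) -> PooledMWResult:
    """Wei-Lachin pooled MW estimate and test.

    ``pooled_theta = w' theta`` with weights summing to one (equal by
    default), ``var = w' Sigma w``; the two-sided p-value refers
    ``(pooled - 0.5) / sqrt(var)`` to the standard normal. A singular or
    zero variance yields a degenerate result without a p-value.
    """
    thetas = np.asarray(thetas, dtype=float).ravel()
    covariance = np.asarray(covariance, dtype=float)
    K = len(thetas)
    if covariance.shape != (K, K):
        raise ValueError("covariance shape does not match thetas")
    if weights is None:
        weights = np.full(K, 1.0 / K)
    else:
        weights = np.asarray(weights, dtype=float).ravel()
        if len(weights) != K:
            raise ValueError("weights length does not match thetas")
        if not math.isclose(weights.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")
    pooled = float(weights @ thetas)
    var = float(weights @ covariance @ weights)
    if var <= 0 or math.isnan(var):
        return PooledMWResult(thetas, covariance, weights, pooled, 0.0,
                              (pooled, pooled), float("nan"), float("nan"),
                              degenerate=True)
    se = math.sqrt(var)
    z = (pooled - 0.5) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    ci = mw_ci(pooled, se, ci_level)
    return PooledMWResult(thetas, covariance, weights, pooled, se, ci, z, p)


def inverse_variance_weights(covariance) -> np.ndarray:
    """Normalized 1/Sigma_kk weights, the configurable alternative to the
    default equal-weight combination."""
    d = np.diag(np.asarray(covariance, dtype=float))
    if np.any(d <= 0):
        raise ValueError("non-positive variance on the diagonal")
    w = 1.0 / d
    return w / w.sum()


def classify_effect(theta: float) -> str:
    """Effect band of a MW estimate: small / medium / large.

    Small is 0.36 <= theta <= 0.64 (both boundaries included); large is
    theta <= 0.29 or theta >= 0.71 (boundaries included); medium is the
    remainder. The bands are symmetric around 0.5, so arm order does not
    change the class.
    """
    lg_lo, sm_lo, sm_hi, lg_hi = EFFECT_BOUNDS
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta {theta!r} outside [0, 1]")
    if theta <= lg_lo or theta >= lg_hi:
        return "large"
    if sm_lo <= theta <= sm_hi:
        return "small"
    return "medium"


def bonferroni(m: int, base_alpha: float = 0.05) -> float:
    """Plain Bonferroni adjustment base_alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return base_alpha / m


def adjust_alpha(family: str, m: Optional[int] = None,
                 base_alpha: float = 0.05) -> float:
    """Adjusted alpha for a registered analysis family, or ``bonferroni(m)``
    for a generic family given ``m``."""
    if family in ALPHA_FAMILIES:
        return ALPHA_FAMILIES[family]
    if m is not None:
        return bonferroni(m, base_alpha)
    raise KeyError(f"unknown multiplicity family {family!r}")
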