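"""Group-comparison decision tree and the two-dimensional two-sample KS test.

Scalar morphometric parameters are compared with a two-sample Student's t
test when both groups pass a Kolmogorov-Smirnov normality check (with
estimated parameters, i.e. Lilliefors) and a two-sample F test for equal
variances; otherwise a Mann-Whitney U test is used.  Orientation
distributions on the (θ, ϕ) half sphere are compared with a non-parametric
two-sample two-dimensional Kolmogorov-Smirnov (Peacock-type) test: the
statistic D is the largest discrepancy between the two empirical quadrant
probabilities, maximized over all four quadrant orientations anchored at
every pooled data point; the p-value comes from label permutations of the
pooled sample (default) or the classical large-sample approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import kolmogorov
from statsmodels.stats.diagnostic import lilliefors

__all__ = ["TestReport", "compare_groups", "ks2d_peacock", "ks2d_statistic"]


@dataclass
class TestReport:
    test_name: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    pre_checks: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _f_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided two-sample F test p-value for equality of variances."""
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    if v1 == 0 or v2 == 0:
        return 0.0
    F = v1 / v2
    df1, df2 = len(x) - 1, len(y) - 1
    p = 2.0 * min(sps.f.cdf(F, df1, df2), sps.f.sf(F, df1, df2))
    return float(min(p, 1.0))


def _normality_p(x: np.ndarray, variant: str = "lilliefors") -> float:
    if np.ptp(x) == 0:
        return 0.0  # a point mass is not normal
    if variant == "lilliefors":
        _, p = lilliefors(x, dist="norm")
    elif variant == "naive":
        _, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    else:
        raise ValueError("variant must be 'lilliefors' or 'naive'")
    return float(p)


def compare_groups(
    x,
    y,
    alpha: float = 0.05,
    normality_variant: str = "lilliefors",
) -> TestReport:
    """Two-group comparison with the normality/variance decision tree.

    A Student's t test is used when both samples pass the KS normality check
    and the F test for variance equality at ``alpha``; otherwise a
    Mann-Whitney U test.  The report records which branch fired and the
    pre-check p-values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per group")
    p_norm_x = _normality_p(x, normality_variant)
    p_norm_y = _normality_p(y, normality_variant)
    p_var = _f_test(x, y)
    pre = {"normality_p_x": p_norm_x, "normality_p_y": p_norm_y, "variance_p": p_var}
    if p_norm_x > alpha and p_norm_y > alpha and p_var > alpha:
        stat, p = sps.ttest_ind(x, y, equal_var=True)
        return TestReport("t_test", float(stat), float(p), len(x), len(y), pre)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        # fully tied samples: exchangeable, no evidence of difference
        return TestReport("mann_whitney", len(x) * len(y) / 2.0, 1.0, len(x), len(y), pre)
    stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestReport("mann_whitney", float(stat), float(p), len(x), len(y), pre)


def _quadrant_matrices(eval_pts: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Boolean membership of data points in the 4 closed quadrants at each
    evaluation point; shape (4, n_eval, n_data)."""
    ex = eval_pts[:, 0][:, None]
    ey = eval_pts[:, 1][:, None]
    dx = data[:, 0][None, :]
    dy = data[:, 1][None, :]
    le_x = dx <= ex
    le_y = dy <= ey
    ge_x = dx >= ex
    ge_y = dy >= ey
    return np.stack([le_x & le_y, le_x & ge_y, ge_x & le_y, ge_x & ge_y])


def ks2d_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """The 2D two-sample KS statistic D.

    Quadrant probabilities are evaluated at every pooled data point, with
    quadrant boundaries closed on the evaluated point; D is the maximum
    absolute difference over quadrants and evaluation points.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    pooled = np.vstack([a, b])
    Q = _quadrant_matrices(pooled, pooled)  # (4, m, m)
    na, nb = len(a), len(b)
    pa = Q[:, :, :na].mean(axis=2)
    pb = Q[:, :, na:].mean(axis=2)
    return float(np.abs(pa - pb).max())


def ks2d_peacock(
    a,
    b,
    p_method: str = "permutation",
    n_perm: int = 2000,
    seed: int = 0,
) -> TestReport:
    """Two-sample two-dimensional KS (Peacock-type) test on (θ, ϕ) pairs.

    ``p_method="permutation"`` permutes the pooled sample labels (default,
    exact under exchangeability); ``"asymptotic"`` uses the classical
    large-sample approximation with the correlation correction.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 points per sample")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("angles must be finite")
    na, nb = len(a), len(b)
    pooled = np.vstack([a, b])
    if np.allclose(pooled, pooled[0]):
        return TestReport("ks2d_peacock", 0.0, 1.0, na, nb, meta={"p_method": p_method})
    D = ks2d_statistic(a, b)
    if p_method == "permutation":
        rng = np.random.default_rng(seed)
        m = na + nb
        Q = _quadrant_matrices(pooled, pooled).astype(np.float32)  # (4, m, m)
        labels = np.zeros((n_perm, m), dtype=np.float32)
        for k in range(n_perm):
            idx = rng.permutation(m)[:na]
            labels[k, idx] = 1.0
        # quadrant probabilities for each permutation via matmul
        d_perm = np.zeros(n_perm, dtype=np.float32)
        for q in range(4):
            ca = Q[q] @ labels.T  # (m, n_perm) counts in sample A
            ct = Q[q].sum(axis=1, keepdims=True)  # total counts
            pa = ca / na
            pb = (ct - ca) / nb
            np.maximum(d_perm, np.abs(pa - pb).max(axis=0), out=d_perm)
        n_gt = float((d_perm > D + 1e-12).sum())
        n_eq = float((np.abs(d_perm - D) <= 1e-12).sum())
        p = (1.0 + n_gt + n_eq) / (n_perm + 1.0)
        # D is discrete, so the standard permutation p is conservative; the
        # mid-p (half weight on ties) is the calibrated diagnostic value
        p_mid = (n_gt + 0.5 * (n_eq + 1.0)) / (n_perm + 1.0)
        meta = {"p_method": "permutation", "n_perm": n_perm, "seed": seed,
                "p_mid": float(p_mid)}
    elif p_method == "asymptotic":
        def _corr(s):
            if len(s) < 2 or np.ptp(s[:, 0]) == 0 or np.ptp(s[:, 1]) == 0:
                return 0.0
            return float(np.corrcoef(s[:, 0], s[:, 1])[0, 1])
        r2 = 0.5 * (_corr(a) ** 2 + _corr(b) ** 2)
        n_eff = na * nb / (na + nb)
        sqn = np.sqrt(n_eff)
        d = D * sqn / (1.0 + np.sqrt(max(1.0 - r2, 0.0)) * (0.25 - 0.75 / sqn))
        p = float(kolmogorov(d))
        meta = {"p_method": "asymptotic"}
    else:
        raise ValueError("p_method must be 'permutation' or 'asymptotic'")
    return TestReport("ks2d_peacock", D, float(np.clip(p, 0.0, 1.0)), na, nb, meta=meta)
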