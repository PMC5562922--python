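"""Group inference on threshold-sweep summaries.

Metric-versus-density curves are collapsed to one number per subject by the
trapezoidal area under the curve (AUC).  Groups are compared with a
label-permutation test on the difference of group means; nodal families are
corrected with Benjamini-Hochberg FDR; brain-behavior relationships are
plain Pearson correlations computed within each group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "curve_auc",
    "permutation_group_test",
    "permutation_group_test_matrix",
    "fdr_bh",
    "behavior_correlation",
    "two_sample_t_from_summary",
]


@dataclass
class GroupComparison:
    """Result of one permutation comparison (one metric at one node, or one
    global metric)."""

    observed_diff: float
    p_two_tailed: float
    n_perm: int
    metric: str = ""
    node: int | str = "global"
    fdr_significant: bool | None = None
    q_level: float | None = None
    null_distribution: np.ndarray | None = field(default=None, repr=False)


def curve_auc(values, densities) -> float:
    """Trapezoidal area under a metric-versus-density curve."""
    v = np.asarray(values, dtype=float)
    d = np.asarray(densities, dtype=float)
    if v.shape[-1] != d.shape[0]:
        raise ValueError("values and densities must have matching length")
    if d.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if np.any(np.diff(d) <= 0):
        raise ValueError("densities must be strictly increasing")
    return float(np.trapezoid(v, d)) if v.ndim == 1 else np.trapezoid(v, d, axis=-1)


def _perm_indicators(n: int, n_a: int, n_perm: int, rng) -> np.ndarray:
    """(n_perm x n) 0/1 matrix; each row selects a random size-n_a subset."""
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, n_a - 1, axis=1)[:, :n_a]
    Z = np.zeros((n_perm, n), dtype=np.float64)
    np.put_along_axis(Z, idx, 1.0, axis=1)
    return Z


def permutation_group_test_matrix(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
):
    """Vectorized permutation test over many variables at once.

    ``values_a`` is (n_a x m), ``values_b`` (n_b x m); returns
    ``(observed_diff, p)`` vectors of length m.  The statistic is
    mean(A) - mean(B); each permutation reassigns the pooled subjects to
    groups of the original sizes; p uses the add-one estimator
    (1 + #{|null| >= |observed|}) / (1 + n_perm).
    """
    if rng is None:
        rng = np.random.default_rng()
    A = np.atleast_2d(np.asarray(values_a, dtype=float))
    B = np.atleast_2d(np.asarray(values_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the variable dimension")
    n_a, n_b = A.shape[0], B.shape[0]
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    pooled = np.vstack([A, B])
    n = n_a + n_b
    observed = A.mean(axis=0) - B.mean(axis=0)
    total = pooled.sum(axis=0)
    Z = _perm_indicators(n, n_a, n_perm, rng)
    sum_a = Z @ pooled  # (n_perm x m)
    null = sum_a * (1.0 / n_a + 1.0 / n_b) - total / n_b
    exceed = (np.abs(null) >= np.abs(observed)[None, :] - 1e-12).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    return observed, p


def permutation_group_test(
    values_a,
    values_b,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
    exact: bool = False,
    keep_null: bool = False,
    metric: str = "",
    node: int | str = "global",
) -> GroupComparison:
    """Permutation test for a difference in group means of scalar values.

    With ``exact=True`` all C(n, n_a) group assignments are enumerated and
    p is the exact fraction whose |difference| is at least the observed
    |difference| (the identity assignment included); only feasible for small
    pooled samples.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical; permutation p set to 1", stacklevel=2)
        return GroupComparison(observed_diff=0.0, p_two_tailed=1.0,
                               n_perm=0, metric=metric, node=node)
    if exact:
        n = pooled.size
        n_assign = math.comb(n, a.size)
        if n_assign > 500_000:
            raise ValueError(f"{n_assign} assignments is too many to enumerate")
        total = pooled.sum()
        count = 0
        nulls = np.empty(n_assign)
        for i, idx in enumerate(combinations(range(n), a.size)):
            sa = pooled[list(idx)].sum()
            diff = sa / a.size - (total - sa) / b.size
            nulls[i] = diff
            if abs(diff) >= abs(observed) - 1e-12:
                count += 1
        return GroupComparison(
            observed_diff=observed, p_two_tailed=count / n_assign,
            n_perm=n_assign, metric=metric, node=node,
            null_distribution=nulls if keep_null else None,
        )
    if rng is None:
        rng = np.random.default_rng()
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    Z = _perm_indicators(pooled.size, a.size, n_perm, rng)
    sum_a = Z @ pooled
    null = sum_a * (1.0 / a.size + 1.0 / b.size) - pooled.sum() / b.size
    exceed = int((np.abs(null) >= abs(observed) - 1e-12).sum())
    p = (1.0 + exceed) / (1.0 + n_perm)
    return GroupComparison(
        observed_diff=observed, p_two_tailed=float(p), n_perm=n_perm,
        metric=metric, node=node,
        null_distribution=null if keep_null else None,
    )


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def behavior_correlation(nodal_auc, scores) -> tuple[float, float]:
    """Pearson correlation (r and two-sided t-based p) between a per-subject
    network summary and behavioral scores; compute within one group at a
    time."""
    x = np.asarray(nodal_auc, dtype=float).ravel()
    y = np.asarray(scores, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def two_sample_t_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> tuple[float, int]:
    """Pooled-variance two-sample t statistic and df from group summaries."""
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("SDs must be positive")
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 per group")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    t = (mean_a - mean_b) / math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    return float(t), df
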