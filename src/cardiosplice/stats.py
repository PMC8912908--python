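"""Shared statistical primitives: vectorized per-feature OLS, exact 2x2 tests
with conditional-MLE odds ratios, and multiple-testing corrections."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagate)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def bonferroni_adjust(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    out[ok] = np.minimum(p[ok] * ok.sum(), 1.0)
    return out


def ols_per_feature(Y: np.ndarray, X: np.ndarray, coef_index: int):
    """OLS of each row of ``Y`` (features x samples) on design ``X`` (samples x p).

    Returns (beta, se, p) for the coefficient at ``coef_index``, with
    two-sided t-test p-values on n - p degrees of freedom.  The design is
    solved once; all features share it.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"design has n={n} <= p={p}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"rank-deficient design: rank {rank} < {p} columns")
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T                      # p x n
    B = Y @ H.T                            # features x p
    resid = Y - B @ X.T
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(sigma2, 0.0)[:, None] * np.diag(XtX_inv)[None, :])
    beta = B[:, coef_index]
    se_c = se[:, coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_c > 0, beta / se_c, np.inf * np.sign(beta))
    pvals = 2.0 * sps.t.sf(np.abs(t), dof)
    return beta, se_c, pvals


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns (conditional-MLE odds ratio, p).  With a zero margin the odds
    ratio is undefined (NaN) and p = 1.
    """
    a, b, c, d = np.asarray(table, dtype=int).ravel()
    tab = np.array([[a, b], [c, d]])
    if min(tab.sum(axis=0).min(), tab.sum(axis=1).min()) == 0:
        return float("nan"), 1.0
    res = sps.contingency.odds_ratio(tab, kind="conditional")
    p = sps.fisher_exact(tab, alternative="two-sided")[1]
    return float(res.statistic), float(p)


def fisher_2x2_ci(table, confidence=0.95):
    """Conditional-MLE OR with exact confidence interval and two-sided p."""
    a, b, c, d = np.asarray(table, dtype=int).ravel()
    tab = np.array([[a, b], [c, d]])
    if min(tab.sum(axis=0).min(), tab.sum(axis=1).min()) == 0:
        return float("nan"), (float("nan"), float("nan")), 1.0
    res = sps.contingency.odds_ratio(tab, kind="conditional")
    ci = res.confidence_interval(confidence_level=confidence)
    p = sps.fisher_exact(tab, alternative="two-sided")[1]
    return float(res.statistic), (float(ci.low), float(ci.high)), float(p)


def fisher_one_sided_greater(table) -> float:
    """One-sided Fisher p that the first row's odds exceed the second's."""
    tab = np.asarray(table, dtype=int).reshape(2, 2)
    return float(sps.fisher_exact(tab, alternative="greater")[1])


def rank_inverse_normal(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Rank-based inverse normal transform of a 1-D vector.

    Uses offset 0.5: Phi^-1((rank - 0.5) / n) with average ranks for ties.
    A constant vector maps to all zeros; the second return value flags that
    degenerate case.
    """
    v = np.asarray(values, dtype=float)
    if np.all(v == v[0]):
        return np.zeros_like(v), True
    ranks = sps.rankdata(v, method="average")
    return sps.norm.ppf((ranks - 0.5) / len(v)), False
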