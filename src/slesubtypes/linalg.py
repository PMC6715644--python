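"""Shared least-squares machinery: batched OLS, nested F-tests, BH FDR.

Every association model in the pipeline (per-CpG cluster ANOVA, per-pair
meQTL fits, CIT component tests, permutation enrichment) is an ordinary
linear model with a shared design matrix across thousands of responses, so
fits are batched through QR projections rather than looped model objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "add_intercept",
    "residualize",
    "rss",
    "nested_f_test",
    "ols_details",
    "bh_adjust",
]


def add_intercept(X: np.ndarray | None, n: int) -> np.ndarray:
    """Column-stack an intercept with an optional covariate block."""
    ones = np.ones((n, 1))
    if X is None or (hasattr(X, "size") and X.size == 0):
        return ones
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([ones, X])


def _q_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of X (rank-revealing)."""
    q, r = np.linalg.qr(np.asarray(X, dtype=float))
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    return q[:, diag > tol]


def effective_rank(X: np.ndarray) -> int:
    return _q_basis(X).shape[1]


def residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Project Y (n x m) onto the orthogonal complement of span(X)."""
    Q = _q_basis(X)
    Y = np.asarray(Y, dtype=float)
    return Y - Q @ (Q.T @ Y)


def rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y regressed on X."""
    R = residualize(Y, X)
    return np.einsum("ij,ij->j", R, R)


def nested_f_test(Y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray):
    """Batched F-test comparing nested designs for every column of Y.

    Returns (F, p, partial_r2, df1, df2).  Columns with zero residual
    variance under the full model get F = 0, p = 1 (degenerate response).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    p_full = effective_rank(X_full)
    p_red = effective_rank(X_reduced)
    df1 = p_full - p_red
    df2 = n - p_full
    if df1 <= 0:
        raise ValueError("full design adds no estimable parameters")
    if df2 <= 0:
        raise ValueError("model is saturated: no residual degrees of freedom")
    rss_full = rss(Y, X_full)
    rss_red = rss(Y, X_reduced)
    delta = np.maximum(rss_red - rss_full, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (delta / df1) / (rss_full / df2)
        partial_r2 = np.where(rss_red > 0, delta / rss_red, 0.0)
    # constant responses carry no information: the ratio of two numerical
    # zeros must not masquerade as signal
    degenerate = ~np.isfinite(F) | (Y.var(axis=0) <= 1e-24)
    F = np.where(degenerate, 0.0, F)
    p = stats.f.sf(F, df1, df2)
    p = np.where(degenerate, 1.0, p)
    return F, p, partial_r2, df1, df2


def ols_details(y: np.ndarray, X: np.ndarray):
    """Single-response OLS with coefficient standard errors.

    Returns (beta, se, t, p, df_resid).  X must be full column rank.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient (perfect collinearity)")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, pvals, df


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bh_series(p: pd.Series) -> pd.Series:
    return pd.Series(bh_adjust(p.to_numpy()), index=p.index)
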