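"""Covariate-adjusted false discovery rates (Storey q-values with a
covariate-dependent null proportion).

The proportion of true nulls pi0 is allowed to depend on an informative
covariate (mean log-CPM for genes, set size for pathways): for each
lambda on a grid, the indicator 1{p > lambda} is regressed on a spline
basis of the covariate by logistic regression, giving pi0_lambda(x); the
estimates are smoothed over lambda and evaluated at the grid maximum.
q-values are the BH step-up values scaled by pi0(x). With pi0 forced to
1 this reduces exactly to Benjamini-Hochberg, which is also the fallback
for small test families.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["qvalue_covariate", "bh_adjust"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural-cubic-like basis: intercept + x + truncated cubics at knots."""
    x = np.asarray(x, dtype=float)
    # winsorize so the cubic terms cannot explode in the covariate tails
    lo, hi = np.quantile(x, [0.05, 0.95])
    x = np.clip(x, lo, hi)
    s = x.std()
    xs = (x - x.mean()) / (s if s > 0 else 1.0)
    cols = [np.ones_like(xs), xs]
    if s > 0 and df > 1:
        knots = np.quantile(xs, np.linspace(0.2, 0.8, df - 1))
        for k in knots:
            cols.append(np.clip(xs - k, 0, None) ** 3)
    return np.column_stack(cols)


def _logistic_fit(B: np.ndarray, y: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Lightly ridge-penalized IRLS logistic regression returning fitted
    probabilities; the penalty (not on the intercept) keeps the covariate
    effect near zero unless the data demand otherwise."""
    beta = np.zeros(B.shape[1])
    ybar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    beta[0] = np.log(ybar / (1 - ybar))
    pen = 1e-2 * len(y) * np.eye(B.shape[1])
    pen[0, 0] = 1e-8
    for _ in range(max_iter):
        eta = np.clip(B @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-9, None)
        z = eta + (y - mu) / w
        Bw = B * w[:, None]
        try:
            new = np.linalg.solve(B.T @ Bw + pen, B.T @ (w * z))
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
    eta = np.clip(B @ beta, -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


def estimate_pi0(
    p: np.ndarray,
    covariate: np.ndarray | None = None,
    lambdas: np.ndarray | None = None,
) -> np.ndarray:
    """Covariate-dependent null-proportion estimate pi0(x) per test."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    if covariate is None:
        covariate = np.zeros(m)
    covariate = np.asarray(covariate, dtype=float)
    B = _spline_basis(covariate)
    pi0_grid = np.empty((len(lambdas), m))
    for i, lam in enumerate(lambdas):
        y = (p > lam).astype(float)
        if y.sum() in (0, m) or B.shape[1] == 2 and covariate.std() == 0:
            prob = np.full(m, y.mean())
        else:
            prob = _logistic_fit(B, y)
        pi0_grid[i] = prob / (1.0 - lam)
    # smooth over lambda with a precision-weighted linear trend (the
    # variance of pi0_lambda grows like lambda / (1 - lambda)), evaluated
    # at the top of the grid
    wts = np.sqrt((1.0 - lambdas) / lambdas)
    L = np.vander(lambdas, 2)
    coef, *_ = np.linalg.lstsq(L * wts[:, None], pi0_grid * wts[:, None], rcond=None)
    pi0 = np.vander(np.array([lambdas[-1]]), 2) @ coef
    return np.clip(pi0.ravel(), 1e-8, 1.0)


def qvalue_covariate(
    p,
    covariate=None,
    min_tests: int = 50,
    pi0: np.ndarray | float | None = None,
) -> np.ndarray:
    """q-values with a covariate-dependent pi0; plain BH for small families.

    ``pi0`` may be supplied (scalar or per-test) to bypass estimation;
    ``pi0=1`` gives exactly the BH adjustment.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    if pi0 is None:
        if m < min_tests:
            warnings.warn(f"only {m} tests; falling back to plain BH")
            return bh_adjust(p)
        pi0_vec = estimate_pi0(p, covariate)
    else:
        pi0_vec = np.broadcast_to(np.asarray(pi0, dtype=float), (m,)).copy()
    scaled = pi0_vec * p
    order = np.argsort(p, kind="mergesort")
    ranked = scaled[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
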