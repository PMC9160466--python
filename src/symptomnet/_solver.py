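"""Penalized logistic regression path solver.

Coordinate descent on the iteratively reweighted least-squares surrogate
(the classic glmnet scheme), jitted with numba because the bootstrap and
permutation machinery re-runs the full network estimation thousands of
times.  The objective for one node is

    f(b0, b) = -(1/n) * sum_i c_i [ y_i eta_i - log(1 + exp(eta_i)) ] + lam * ||b||_1

with eta = b0 + X b, an unpenalized intercept, and observation frequency
weights ``c`` (n = sum c).  Binary designs have at most 2^p distinct rows,
so callers compress data to unique patterns with counts and the solver
cost becomes independent of the subject count.  Soft-thresholding yields
exact zeros, so edge presence needs no epsilon test.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["logistic_lasso_path", "logistic_loglik", "lambda_max", "compress_binary"]

_WEIGHT_FLOOR = 1e-5
_PROB_CLIP = 1e-9


def compress_binary(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a 0/1 matrix to its unique row patterns and counts.

    Returns ``(patterns, counts)`` with ``patterns`` float64 of shape
    ``(K, p)`` and integer ``counts`` summing to the row count.
    """
    n, p = values.shape
    if p <= 63:
        codes = values.astype(np.uint64) @ (np.uint64(1) << np.arange(p, dtype=np.uint64))
        uniq, inverse, counts = np.unique(codes, return_inverse=True, return_counts=True)
        patterns = ((uniq[:, None] >> np.arange(p, dtype=np.uint64)) & 1).astype(np.float64)
    else:
        patterns, inverse, counts = np.unique(
            values, axis=0, return_inverse=True, return_counts=True
        )
        patterns = patterns.astype(np.float64)
    return np.ascontiguousarray(patterns), counts.astype(np.float64)


@njit(cache=True, fastmath=True)
def _update_coord(XT, w, r, beta, lam, v, n, j):
    """One soft-threshold update of coordinate j; returns the step size."""
    K = XT.shape[1]
    num = 0.0
    for i in range(K):
        if XT[j, i] != 0.0:
            num += w[i] * XT[j, i] * r[i]
    num = num / n + v[j] * beta[j]
    if num > lam:
        new = (num - lam) / v[j]
    elif num < -lam:
        new = (num + lam) / v[j]
    else:
        new = 0.0
    diff = new - beta[j]
    if diff != 0.0:
        for i in range(K):
            if XT[j, i] != 0.0:
                r[i] -= XT[j, i] * diff
        beta[j] = new
    return abs(diff) * v[j]


@njit(cache=True, fastmath=True)
def _update_intercept(w, r, beta0, wsum):
    K = r.shape[0]
    num0 = 0.0
    for i in range(K):
        num0 += w[i] * r[i]
    shift = num0 / wsum
    if shift != 0.0:
        for i in range(K):
            r[i] -= shift
    return beta0 + shift, abs(shift)


@njit(cache=True, fastmath=True)
def _inner_cd(XT, w, r, beta, beta0, lam, v, n, tol, max_iter):
    """Weighted coordinate descent on the least-squares surrogate.

    ``r`` is the working residual (z - b0 - X b), updated in place; ``w``
    already includes the frequency weights.  Full passes alternate with
    passes restricted to the currently-nonzero (active) coordinates.
    Returns the updated intercept.
    """
    d = XT.shape[0]
    wsum = w.sum()
    for _ in range(max_iter):
        # full pass over all coordinates
        delta_max = 0.0
        for j in range(d):
            if v[j] <= 1e-12:
                continue
            step = _update_coord(XT, w, r, beta, lam, v, n, j)
            if step > delta_max:
                delta_max = step
        beta0, step = _update_intercept(w, r, beta0, wsum)
        if step > delta_max:
            delta_max = step
        if delta_max < tol:
            break
        # active-set passes until stable
        for _ in range(max_iter):
            delta_a = 0.0
            for j in range(d):
                if beta[j] == 0.0 or v[j] <= 1e-12:
                    continue
                step = _update_coord(XT, w, r, beta, lam, v, n, j)
                if step > delta_a:
                    delta_a = step
            beta0, step = _update_intercept(w, r, beta0, wsum)
            if step > delta_a:
                delta_a = step
            if delta_a < tol:
                break
    return beta0


@njit(cache=True, fastmath=True)
def logistic_lasso_path(X, y, counts, lambdas, tol=1e-6, max_outer=50, max_inner=100):
    """Solve the L1 logistic problem along a (descending) penalty path.

    Parameters
    ----------
    X : (K, d) float64 design matrix of unique patterns (no intercept column).
    y : (K,) float64 vector of 0/1 responses per pattern.
    counts : (K,) float64 frequency weights (n = counts.sum()).
    lambdas : descending penalty values.

    Returns
    -------
    intercepts : (L,) array
    coefs : (L, d) array with exact zeros
    logliks : (L,) total (not per-observation) logistic log-likelihoods
    """
    K, d = X.shape
    L = lambdas.shape[0]
    coefs = np.zeros((L, d))
    intercepts = np.zeros(L)
    logliks = np.zeros(L)
    n = counts.sum()

    ybar = 0.0
    for i in range(K):
        ybar += counts[i] * y[i]
    ybar /= n
    if ybar <= 0.0 or ybar >= 1.0:
        # degenerate response: null model at every lambda
        cap = 30.0 if ybar >= 1.0 else -30.0
        ll = 0.0
        for i in range(K):
            ll += counts[i] * (y[i] * cap - np.log(1.0 + np.exp(cap)))
        for k in range(L):
            intercepts[k] = cap
            logliks[k] = ll
        return intercepts, coefs, logliks

    XT = np.ascontiguousarray(X.T)
    beta = np.zeros(d)
    beta0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(K, beta0)
    w = np.empty(K)
    r = np.empty(K)
    v = np.empty(d)

    for k in range(L):
        lam = lambdas[k]
        for _ in range(max_outer):
            # quadratic surrogate at current eta
            for i in range(K):
                p = 1.0 / (1.0 + np.exp(-eta[i]))
                if p < _PROB_CLIP:
                    p = _PROB_CLIP
                elif p > 1.0 - _PROB_CLIP:
                    p = 1.0 - _PROB_CLIP
                wi = p * (1.0 - p)
                if wi < _WEIGHT_FLOOR:
                    wi = _WEIGHT_FLOOR
                w[i] = counts[i] * wi
                r[i] = (y[i] - p) / wi  # z - eta
            for j in range(d):
                s = 0.0
                for i in range(K):
                    if XT[j, i] != 0.0:
                        s += w[i] * XT[j, i] * XT[j, i]
                v[j] = s / n
            old_beta0 = beta0
            old_beta = beta.copy()
            beta0 = _inner_cd(XT, w, r, beta, beta0, lam, v, n, tol, max_inner)
            # refresh eta from scratch to avoid drift
            for i in range(K):
                eta[i] = beta0
            for j in range(d):
                if beta[j] != 0.0:
                    for i in range(K):
                        if XT[j, i] != 0.0:
                            eta[i] += XT[j, i] * beta[j]
            change = abs(beta0 - old_beta0)
            for j in range(d):
                cch = abs(beta[j] - old_beta[j])
                if cch > change:
                    change = cch
            if change < 10.0 * tol:
                break
        intercepts[k] = beta0
        coefs[k] = beta
        ll = 0.0
        for i in range(K):
            e = eta[i]
            if e > 30.0:
                ll += counts[i] * (y[i] * e - e)
            else:
                ll += counts[i] * (y[i] * e - np.log(1.0 + np.exp(e)))
        logliks[k] = ll
    return intercepts, coefs, logliks


def logistic_loglik(
    X: np.ndarray,
    y: np.ndarray,
    intercept: float,
    beta: np.ndarray,
    counts: np.ndarray | None = None,
) -> float:
    """Total logistic log-likelihood at given coefficients."""
    eta = intercept + X @ beta
    terms = y * eta - np.logaddexp(0.0, eta)
    if counts is not None:
        terms = counts * terms
    return float(np.sum(terms))


def lambda_max(X: np.ndarray, y: np.ndarray, counts: np.ndarray | None = None) -> float:
    """Smallest penalty at which every (penalized) coefficient is zero.

    With the intercept fitted, this is the max absolute gradient of the
    unpenalized loss at the intercept-only solution: max_j |x_j' c (y - ybar)|/n.
    """
    if counts is None:
        counts = np.ones(X.shape[0])
    n = counts.sum()
    ybar = float(counts @ y) / n
    if ybar <= 0.0 or ybar >= 1.0:
        return 0.0
    return float(np.max(np.abs(X.T @ (counts * (y - ybar)))) / n)
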