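"""Coordinate-descent solver for elastic-net penalized logistic regression.

Implements the standard IRLS + cyclic coordinate descent scheme with warm
starts along a decreasing lambda path and active-set iteration, on
column-standardized inputs.  The objective per lambda is

    -(1/n) sum_i [y_i eta_i - log(1 + exp(eta_i))]
        + lam * (alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2)

with eta = b0 + X b.  Written for small dense problems (hundreds of cells by
hundreds of genes) where a cross-validated path over several alphas and many
repetitions must stay fast on one CPU.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PMIN = 1e-5


@njit(cache=True)
def _sweep(XT, w, r, beta, wx2, l1, l2, idx, n):
    """One cyclic coordinate-descent pass over the features in ``idx``;
    returns the largest absolute coefficient change."""
    max_delta = 0.0
    for jj in range(idx.shape[0]):
        j = idx[jj]
        bj = beta[j]
        rho = bj * wx2[j]
        for i in range(n):
            rho += w[i] * XT[j, i] * r[i]
        if rho > l1:
            bj_new = (rho - l1) / (wx2[j] + l2)
        elif rho < -l1:
            bj_new = (rho + l1) / (wx2[j] + l2)
        else:
            bj_new = 0.0
        diff = bj_new - bj
        if diff != 0.0:
            for i in range(n):
                r[i] -= XT[j, i] * diff
            beta[j] = bj_new
            if abs(diff) > max_delta:
                max_delta = abs(diff)
    return max_delta


@njit(cache=True)
def _cd_path(XT, y, alpha, lambdas, max_irls, tol):
    """Warm-started lambda path.

    XT is (p, n) C-contiguous (features by samples, standardized columns).
    Returns (coefs [n_lambda, p], intercepts [n_lambda], converged flags).
    """
    p, n = XT.shape
    n_lam = lambdas.shape[0]
    coefs = np.zeros((n_lam, p))
    b0s = np.zeros(n_lam)
    ok = np.ones(n_lam, dtype=np.bool_)
    all_idx = np.arange(p)

    ybar = y.mean()
    if ybar < _PMIN:
        ybar = _PMIN
    if ybar > 1 - _PMIN:
        ybar = 1 - _PMIN
    beta = np.zeros(p)
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)

    for li in range(n_lam):
        lam = lambdas[li]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        converged = False
        for _ in range(max_irls):
            w = np.empty(n)
            z = np.empty(n)
            for i in range(n):
                pi = 1.0 / (1.0 + np.exp(-eta[i]))
                if pi < _PMIN:
                    pi = _PMIN
                elif pi > 1.0 - _PMIN:
                    pi = 1.0 - _PMIN
                wi = pi * (1.0 - pi)
                w[i] = wi / n
                z[i] = eta[i] + (y[i] - pi) / wi
            wsum = w.sum()
            r = z - eta
            wx2 = np.empty(p)
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * XT[j, i] * XT[j, i]
                wx2[j] = s
            irls_delta = 0.0
            for cycle in range(100):
                d_full = _sweep(XT, w, r, beta, wx2, l1, l2, all_idx, n)
                # intercept
                num = 0.0
                for i in range(n):
                    num += w[i] * r[i]
                d0 = num / wsum
                if d0 != 0.0:
                    b0 += d0
                    for i in range(n):
                        r[i] -= d0
                d_full = max(d_full, abs(d0))
                if cycle == 0:
                    irls_delta = d_full
                if d_full < tol:
                    break
                active = np.flatnonzero(beta)
                for _inner in range(1000):
                    d_act = _sweep(XT, w, r, beta, wx2, l1, l2, active, n)
                    num = 0.0
                    for i in range(n):
                        num += w[i] * r[i]
                    d0 = num / wsum
                    if d0 != 0.0:
                        b0 += d0
                        for i in range(n):
                            r[i] -= d0
                    if max(d_act, abs(d0)) < tol:
                        break
            eta = z - r
            if irls_delta < tol * 10.0:
                converged = True
                break
        coefs[li] = beta
        b0s[li] = b0
        ok[li] = converged
    return coefs, b0s, ok


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda that zeroes every coefficient (standardized X)."""
    n = X.shape[0]
    ybar = y.mean()
    grad = np.abs(X.T @ (y - ybar)) / n
    return float(grad.max() / max(alpha, 1e-3))


def lambda_path(
    X: np.ndarray, y: np.ndarray, alpha: float,
    n_lambda: int = 30, min_ratio: float = 0.01,
) -> np.ndarray:
    lmax = lambda_max(X, y, alpha)
    return lmax * np.logspace(0.0, np.log10(min_ratio), n_lambda)


def fit_path(
    X: np.ndarray, y: np.ndarray, alpha: float, lambdas: np.ndarray,
    max_irls: int = 8, tol: float = 1e-4,
):
    """Fit the penalized logistic path on standardized X (n, p)."""
    XT = np.ascontiguousarray(X.T, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    coefs, b0s, ok = _cd_path(XT, y, alpha, lambdas, max_irls, tol)
    return coefs, b0s, ok


def predict_proba(X: np.ndarray, coef: np.ndarray, intercept: float) -> np.ndarray:
    eta = intercept + X @ coef
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


def binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    p = np.clip(prob, _PMIN, 1 - _PMIN)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
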