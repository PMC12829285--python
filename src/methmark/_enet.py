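"""Multinomial elastic-net solver: coordinate descent along a lambda path.

Minimises, over per-class coefficient vectors B (K x p) and unpenalized
intercepts b0,

    (1/n) sum_i -log softmax(b0 + B x_i)_{y_i}
      + lambda * sum_{j,k} [ alpha |B_kj| + (1-alpha)/2 B_kj^2 ]

by partial Newton steps: holding the other classes fixed, each class's
block is updated by cyclic coordinate descent on the weighted
least-squares approximation (weights p(1-p), working response from the
current linear predictor), exactly the classical path algorithm for
penalized GLMs. Paths are solved from lambda_max downward with warm
starts, which keeps each step to a handful of passes. Probabilities are
clamped away from 0/1 so Newton weights stay bounded.

The compiled kernels carry no state; everything deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_P_CLAMP = 1e-5
_W_MIN = 1e-5


@njit(cache=True)
def _softmax(eta):
    n, k = eta.shape
    out = np.empty_like(eta)
    for i in range(n):
        m = eta[i].max()
        s = 0.0
        for c in range(k):
            out[i, c] = np.exp(eta[i, c] - m)
            s += out[i, c]
        for c in range(k):
            out[i, c] /= s
    return out


@njit(cache=True)
def _cd_pass(X, r, w, b, wx2, lam_l1, lam_l2, active_only):
    """One coordinate-descent sweep; returns the largest update."""
    n, p = X.shape
    max_delta = 0.0
    for j in range(p):
        if active_only and b[j] == 0.0:
            continue
        num = 0.0
        for i in range(n):
            num += w[i] * X[i, j] * r[i]
        num = num / n + wx2[j] * b[j]
        if num > lam_l1:
            new = (num - lam_l1) / (wx2[j] + lam_l2)
        elif num < -lam_l1:
            new = (num + lam_l1) / (wx2[j] + lam_l2)
        else:
            new = 0.0
        d = new - b[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= d * X[i, j]
            b[j] = new
            ad = abs(d)
            if ad > max_delta:
                max_delta = ad
    return max_delta


@njit(cache=True)
def _cd_class(X, r, w, b, lam_l1, lam_l2, tol, max_pass):
    """Coordinate descent for one class's weighted LS block.

    Active-set strategy: a full sweep over all features, then sweeps
    over the nonzero support until stable, then a final full sweep to
    verify the optimality conditions (repeated if it activates new
    features). ``r`` is the residual (z - b0 - X b), updated in place.
    Returns the intercept shift.
    """
    n, p = X.shape
    wx2 = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * X[i, j]
        wx2[j] = s / n
    w_sum = w.sum()
    b0_shift = 0.0
    passes = 0
    while passes < max_pass:
        delta = _cd_pass(X, r, w, b, wx2, lam_l1, lam_l2, False)
        passes += 1
        # intercept (unpenalized)
        num = 0.0
        for i in range(n):
            num += w[i] * r[i]
        d0 = num / w_sum
        if d0 != 0.0:
            for i in range(n):
                r[i] -= d0
            b0_shift += d0
            if abs(d0) > delta:
                delta = abs(d0)
        if delta < tol:
            break
        # iterate the active set to convergence, then re-check all
        while passes < max_pass:
            delta = _cd_pass(X, r, w, b, wx2, lam_l1, lam_l2, True)
            passes += 1
            if delta < tol:
                break
    return b0_shift


@njit(cache=True)
def enet_path(X, y_idx, n_classes, lam_path, alpha, tol, max_outer, max_pass):
    """Solve the penalized multinomial model along a decreasing lambda path.

    Returns ``(B0, B)`` with shapes (L, K) and (L, K, p); entry l holds
    the solution at ``lam_path[l]``, warm-started from entry l-1. The
    path stops early once the model explains 99.5% of the null deviance
    (near-saturated fits on separable data never converge and carry no
    additional selection information); remaining entries repeat the last
    solved solution.
    """
    n, p = X.shape
    K = n_classes
    L = lam_path.shape[0]
    B = np.zeros((L, K, p))
    B0 = np.zeros((L, K))

    Y = np.zeros((n, K))
    counts = np.zeros(K)
    for i in range(n):
        Y[i, y_idx[i]] = 1.0
        counts[y_idx[i]] += 1.0
    b = np.zeros((K, p))
    b0 = np.log(counts / n)
    b0 -= b0.mean()

    null_dev = 0.0
    for i in range(n):
        null_dev -= np.log(counts[y_idx[i]] / n)
    null_dev /= n

    eta = np.empty((n, K))
    stopped = -1
    for l in range(L):
        lam = lam_path[l]
        lam_l1 = lam * alpha
        lam_l2 = lam * (1.0 - alpha)
        for _ in range(max_outer):
            for i in range(n):
                for c in range(K):
                    s = b0[c]
                    for j in range(p):
                        s += X[i, j] * b[c, j]
                    eta[i, c] = s
            P = _softmax(eta)
            outer_delta = 0.0
            for c in range(K):
                w = np.empty(n)
                r = np.empty(n)
                for i in range(n):
                    pc = P[i, c]
                    if pc < _P_CLAMP:
                        pc = _P_CLAMP
                    elif pc > 1.0 - _P_CLAMP:
                        pc = 1.0 - _P_CLAMP
                    wi = pc * (1.0 - pc)
                    if wi < _W_MIN:
                        wi = _W_MIN
                    w[i] = wi
                    # working response z minus current fit = residual
                    r[i] = (Y[i, c] - P[i, c]) / wi
                b_old = b[c].copy()
                b0_old = b0[c]
                shift = _cd_class(X, r, w, b[c], lam_l1, lam_l2, tol, max_pass)
                b0[c] += shift
                d = abs(b0[c] - b0_old)
                if d > outer_delta:
                    outer_delta = d
                for j in range(p):
                    d = abs(b[c, j] - b_old[j])
                    if d > outer_delta:
                        outer_delta = d
            if outer_delta < tol:
                break
        B[l] = b
        B0[l] = b0
        # training deviance for the early-stop rule
        for i in range(n):
            for c in range(K):
                s = b0[c]
                for j in range(p):
                    s += X[i, j] * b[c, j]
                eta[i, c] = s
        P = _softmax(eta)
        dev = 0.0
        for i in range(n):
            pi = P[i, y_idx[i]]
            if pi < 1e-15:
                pi = 1e-15
            dev -= np.log(pi)
        dev /= n
        if dev < 0.005 * null_dev:
            stopped = l
            break
    if stopped >= 0:
        for l in range(stopped + 1, L):
            B[l] = B[stopped]
            B0[l] = B0[stopped]
    return B0, B


def lambda_max(X: np.ndarray, y_idx: np.ndarray, n_classes: int, alpha: float) -> float:
    """Smallest lambda with an all-zero coefficient solution.

    At the intercept-only optimum the class probabilities equal the
    training frequencies; all coefficients stay at zero while
    lambda * alpha dominates the largest absolute score entry
    ``(1/n) X^T (Y - P)``.
    """
    n = X.shape[0]
    Y = np.zeros((n, n_classes))
    Y[np.arange(n), y_idx] = 1.0
    p0 = Y.mean(axis=0)
    grad = X.T @ (Y - p0) / n
    return float(np.abs(grad).max()) / max(alpha, 1e-3)


def predict_proba(X: np.ndarray, b0: np.ndarray, b: np.ndarray) -> np.ndarray:
    eta = b0 + X @ b.T
    eta -= eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=1, keepdims=True)


def multinomial_deviance(X, y_idx, b0, b) -> float:
    """Mean negative log-likelihood (half-deviance per observation)."""
    prob = predict_proba(X, b0, b)
    p = np.clip(prob[np.arange(len(y_idx)), y_idx], 1e-15, None)
    return float(-np.log(p).mean())


def objective(X, y_idx, b0, b, lam, alpha) -> float:
    """Penalized objective, for solver cross-checks."""
    pen = alpha * np.abs(b).sum() + 0.5 * (1 - alpha) * (b**2).sum()
    return multinomial_deviance(X, y_idx, b0, b) + lam * pen
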