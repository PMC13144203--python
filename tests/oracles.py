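"""Independent reference computations used to check the package.

These deliberately avoid the package's own evaluation paths: dense double
loops for the objectives, a projected-gradient solver for the inner Poisson
regression, and exhaustive permutation search for topic matching.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def dense_pnmf_objective(Xdense: np.ndarray, H: np.ndarray, W: np.ndarray) -> float:
    """sum_ij lambda_ij - x_ij log lambda_ij by explicit double loop."""
    n, m = Xdense.shape
    total = 0.0
    for i in range(n):
        for j in range(m):
            lam = float(H[i] @ W[j])
            total += lam
            if Xdense[i, j] > 0:
                total -= Xdense[i, j] * math.log(lam)
    return total


def dense_mtm_objective(Xdense: np.ndarray, L: np.ndarray, F: np.ndarray) -> float:
    n, m = Xdense.shape
    total = 0.0
    for i in range(n):
        for j in range(m):
            if Xdense[i, j] > 0:
                total -= Xdense[i, j] * math.log(float(L[i] @ F[j]))
    return total


def poisreg_objective(A: np.ndarray, y: np.ndarray, b: np.ndarray) -> float:
    mu = A @ b
    pos = y > 0
    if np.any(mu[pos] <= 0):
        return np.inf
    return float(mu.sum() - y[pos] @ np.log(mu[pos]))


def projected_gradient_poisreg(
    A: np.ndarray,
    y: np.ndarray,
    b0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 50000,
) -> np.ndarray:
    """Projected gradient with Armijo backtracking for min_{b>=0} of the
    Poisson regression negative log-likelihood."""
    b = np.asarray(b0, dtype=float).copy()
    f = poisreg_objective(A, y, b)
    step = 1.0
    for _ in range(max_iter):
        mu = A @ b
        r = np.zeros_like(y)
        pos = y > 0
        r[pos] = y[pos] / np.maximum(mu[pos], 1e-300)
        g = A.sum(axis=0) - A.T @ r
        # projected-gradient optimality: stop when no feasible descent
        pg = np.where(b > 0, g, np.minimum(g, 0.0))
        if np.max(np.abs(pg)) < tol:
            break
        step = min(step * 2.0, 1e8)
        while True:
            b_new = np.maximum(0.0, b - step * g)
            f_new = poisreg_objective(A, y, b_new)
            if f_new <= f - 1e-4 * float(g @ (b - b_new)) or step < 1e-18:
                break
            step /= 2.0
        if not np.any(b_new != b):
            break
        b, f = b_new, f_new
    return b


def brute_force_match(F_est: np.ndarray, F_true: np.ndarray):
    """Best column permutation by exhaustive search over all K! assignments."""
    K = F_true.shape[1]
    norm_e = F_est / np.linalg.norm(F_est, axis=0, keepdims=True)
    norm_t = F_true / np.linalg.norm(F_true, axis=0, keepdims=True)
    C = norm_e.T @ norm_t
    best_perm, best_total = None, -np.inf
    for perm in itertools.permutations(range(K)):
        total = sum(C[perm[k], k] for k in range(K))
        if total > best_total:
            best_total, best_perm = total, perm
    sims = np.array([C[best_perm[k], k] for k in range(K)])
    return np.array(best_perm), sims
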