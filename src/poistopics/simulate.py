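"""Synthetic count data with known ground truth, plus topic matching.

Two generators mirror the two generative models: multinomial documents over
a topic mixture (rows of fixed total), and Poisson counts under a low-rank
rate matrix. The topic generator plants disjoint "anchor" terms per topic --
terms carrying elevated, topic-exclusive mass -- so the ground truth is
identifiability-friendly and recovery experiments are meaningful. Since
topic order is arbitrary in both models, recovered factors are compared to
the truth after an optimal column matching.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment

from .data import CountMatrix

__all__ = ["simulate_topic_data", "simulate_pnmf_data", "match_topics"]


def _check_dims(n: int, m: int, K: int) -> None:
    if K < 2:
        raise ValueError("K must be >= 2")
    if n < K or m < K:
        raise ValueError("need n >= K and m >= K")


def simulate_topic_data(
    n: int,
    m: int,
    K: int,
    doc_size,
    separation: float = 0.8,
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray, np.ndarray]:
    """Draw documents from the multinomial topic model with known (L, F).

    Each topic k receives a disjoint block of ceil(separation * m / K)
    anchor terms (capped at floor(m / K) so blocks stay disjoint); a
    fraction ``separation`` of the topic's mass is a Dirichlet(1) draw over
    its anchors, the rest a Dirichlet(1) draw over all terms. separation=1
    gives fully disjoint topic supports; separation=0 gives unstructured
    topics. Rows of L are Dirichlet(1); row i of X is multinomial with size
    ``doc_size`` (scalar or per-document vector) and probabilities
    (L F^T)_i, so every row sum equals its document size exactly.
    """
    _check_dims(n, m, K)
    if not (0.0 <= separation <= 1.0):
        raise ValueError("separation must lie in [0, 1]")
    sizes = np.broadcast_to(np.asarray(doc_size, dtype=np.int64), (n,)).copy()
    if np.any(sizes < 1):
        raise ValueError("doc_size must be >= 1")
    rng = np.random.default_rng(seed)

    n_anchor = min(math.ceil(separation * m / K), m // K) if separation > 0 else 0
    F = np.empty((m, K))
    for k in range(K):
        base = rng.dirichlet(np.ones(m))
        if n_anchor > 0:
            anchor = np.zeros(m)
            idx = np.arange(k * n_anchor, (k + 1) * n_anchor)
            anchor[idx] = rng.dirichlet(np.ones(n_anchor))
            F[:, k] = (1.0 - separation) * base + separation * anchor
        else:
            F[:, k] = base
    L = rng.dirichlet(np.ones(K), size=n)

    Pi = L @ F.T
    X = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        X[i] = rng.multinomial(sizes[i], Pi[i])
    return CountMatrix(sp.csr_matrix(X)), L, F


def simulate_pnmf_data(
    n: int,
    m: int,
    K: int,
    scale: float = 1.0,
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray, np.ndarray]:
    """Draw counts from the Poisson NMF model with known (H, W).

    H and W are elementwise unit-exponential (gamma shape 1) draws, with W
    rescaled so the grand mean of the rate matrix H W^T equals ``scale``;
    x_ij ~ Pois((H W^T)_ij). H and W are strictly positive almost surely.
    """
    _check_dims(n, m, K)
    if not (scale > 0):
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    H = rng.gamma(1.0, 1.0, size=(n, K))
    W = rng.gamma(1.0, 1.0, size=(m, K))
    mean_rate = float(H.sum(axis=0) @ W.sum(axis=0)) / (n * m)
    W *= scale / mean_rate
    lam = H @ W.T
    X = rng.poisson(lam)
    return CountMatrix(sp.csr_matrix(X)), H, W


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.linalg.norm(A, axis=0, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=0, keepdims=True)
    return An.T @ Bn


def match_topics(F_est, F_true) -> tuple[np.ndarray, np.ndarray]:
    """Optimally match estimated factor columns to the true ones.

    Solves the assignment problem maximizing the total cosine similarity
    between matched columns. Returns ``(perm, sims)`` such that
    ``F_est[:, perm[k]]`` is the estimate matched to true topic k, and
    ``sims[k]`` is their cosine similarity.
    """
    F_est = np.asarray(F_est, dtype=float)
    F_true = np.asarray(F_true, dtype=float)
    if F_est.shape != F_true.shape:
        raise ValueError(
            f"shape mismatch: estimated {F_est.shape} vs true {F_true.shape}"
        )
    C = _cosine_matrix(F_est, F_true)  # C[a, b] = cos(est a, true b)
    est_idx, true_idx = linear_sum_assignment(-C)
    perm = np.empty(F_true.shape[1], dtype=np.int64)
    perm[true_idx] = est_idx
    sims = C[perm, np.arange(F_true.shape[1])]
    return perm, sims
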