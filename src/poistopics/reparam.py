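"""Change of variables between Poisson NMF and topic-model parameters.

Poisson NMF parameters (H, W) and multinomial topic-model parameters
(L, F, s, u) describe the same rank-K factorization of the expected counts:
pulling the column scales u out of W gives the column-stochastic factors F,
and pulling the row scales s out of H diag(u) gives the row-stochastic
loadings L, so that H W^T = diag(s) L F^T exactly. The map is a bijection
whenever no row/column collapses to zero, which is what lets any Poisson NMF
solver double as a topic-model maximum-likelihood solver.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MappingError",
    "normalize_rows",
    "normalize_cols",
    "pnmf_to_mtm",
    "mtm_to_pnmf",
]


class MappingError(ValueError):
    """The reparameterization is undefined (an all-zero row or column)."""


def normalize_rows(A) -> tuple[np.ndarray, np.ndarray]:
    """Split a non-negative matrix into a row-stochastic part and row sums.

    Returns ``(B, y)`` with ``y_i = sum_j a_ij`` and ``b_ij = a_ij / y_i``,
    so that ``diag(y) @ B`` reconstructs ``A``.
    """
    A = np.asarray(A, dtype=float)
    y = A.sum(axis=1)
    bad = ~(y > 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise MappingError(f"row {i} has no positive element")
    return A / y[:, None], y


def normalize_cols(A) -> tuple[np.ndarray, np.ndarray]:
    """Column analogue of :func:`normalize_rows`: ``B @ diag(y)`` equals A."""
    A = np.asarray(A, dtype=float)
    y = A.sum(axis=0)
    bad = ~(y > 0)
    if bad.any():
        j = int(np.flatnonzero(bad)[0])
        raise MappingError(f"column {j} has no positive element")
    return A / y[None, :], y


def pnmf_to_mtm(H, W) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Map Poisson NMF parameters (H, W) to topic-model parameters (L, F, s, u).

    Columns of W are normalized first (yielding the topic scales u and the
    column-stochastic F), then rows of ``H diag(u)`` (yielding the document
    scales s and the row-stochastic L). Consequently
    ``(H W^T)_ij = s_i (L F^T)_ij`` exactly: the Poisson rates factor into a
    per-document scale times multinomial probabilities.
    """
    H = np.asarray(H, dtype=float)
    W = np.asarray(W, dtype=float)
    F, u = normalize_cols(W)
    L, s = normalize_rows(H * u[None, :])
    return L, F, s, u


def mtm_to_pnmf(L, F, s, u) -> tuple[np.ndarray, np.ndarray]:
    """Inverse map: ``W = F diag(u)``, ``H = diag(s) L diag(u)^-1``."""
    L = np.asarray(L, dtype=float)
    F = np.asarray(F, dtype=float)
    s = np.asarray(s, dtype=float).ravel()
    u = np.asarray(u, dtype=float).ravel()
    if not np.all(u > 0):
        raise ValueError("all topic scales u must be positive")
    if not np.all(s > 0):
        raise ValueError("all document scales s must be positive")
    W = F * u[None, :]
    H = (s[:, None] * L) / u[None, :]
    return H, W
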