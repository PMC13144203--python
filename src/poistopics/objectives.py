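"""Objective functions and log-likelihoods for Poisson NMF and topic models.

All evaluations cost O(nnz(X) + (n + m) K): the linear term sum_ij lambda_ij
of the Poisson objective collapses to the dot product of the column sums of H
and W, and logarithms are taken only at stored nonzeros. Objectives follow
the optimization convention (negative log-likelihood with model-independent
constants dropped); the full log-likelihoods, constants included, are
separate functions so the exact Poisson/multinomial likelihood identity can
be checked with nothing omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data import CountMatrix
from .reparam import pnmf_to_mtm

__all__ = [
    "EvaluationError",
    "PenaltyParams",
    "pnmf_objective",
    "mtm_objective",
    "augmented_objective",
    "pnmf_loglik",
    "mtm_loglik",
    "lemma_identity_gap",
    "penalized_pnmf_objective",
    "penalized_mtm_objective",
]


class EvaluationError(ArithmeticError):
    """An objective is infinite (zero rate at a positive count, etc.)."""


@dataclass
class PenaltyParams:
    """Hyperparameters of the equivalence-preserving penalties.

    ``dirichlet_a`` are Dirichlet shape parameters a_jk >= 1 on the factor
    matrix (F or W); ``gamma_b`` are gamma rate parameters b_k >= 0 on W.
    The defaults (a = 1, b = 0) make every penalty vanish, recovering plain
    maximum likelihood. With a > 1 and b > 0 the penalized Poisson NMF
    objective corresponds to MAP estimation with gamma priors on W, and the
    penalized topic-model objective to MAP estimation with Dirichlet priors
    on the columns of F; the two remain equivalent under the change of
    variables.

    Shapes broadcast: ``dirichlet_a`` may be a scalar or an (m, K) matrix,
    ``gamma_b`` a scalar or a length-K vector.
    """

    dirichlet_a: float | np.ndarray = 1.0
    gamma_b: float | np.ndarray = field(default=0.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.dirichlet_a, dtype=float)
        b = np.asarray(self.gamma_b, dtype=float)
        if np.any(a < 1):
            raise ValueError("Dirichlet shapes a_jk must be >= 1")
        if np.any(b < 0):
            raise ValueError("gamma rates b_k must be >= 0")
        self.dirichlet_a = a if a.ndim else float(a)
        self.gamma_b = b if b.ndim else float(b)

    @property
    def is_null(self) -> bool:
        return bool(np.all(np.asarray(self.dirichlet_a) == 1.0)) and bool(
            np.all(np.asarray(self.gamma_b) == 0.0)
        )

    def shape_matrix(self, m: int, K: int) -> np.ndarray:
        """Dirichlet shapes broadcast to an (m, K) matrix."""
        return np.broadcast_to(np.asarray(self.dirichlet_a, dtype=float), (m, K)).copy()

    def rate_vector(self, K: int) -> np.ndarray:
        """Gamma rates broadcast to a length-K vector."""
        return np.broadcast_to(np.asarray(self.gamma_b, dtype=float), (K,)).copy()


# ----------------------------------------------------------------------
# helpers


def _as_count_matrix(X) -> CountMatrix:
    return X if isinstance(X, CountMatrix) else CountMatrix(X)


def _rates_at_nonzeros(X: CountMatrix, R, C, label: str) -> tuple[np.ndarray, np.ndarray]:
    """Rates (R C^T)_ij at the stored nonzeros of X; errors if any is <= 0."""
    rows, cols, vals = X.triplets()
    rates = np.einsum("nk,nk->n", R[rows], C[cols])
    bad = ~(rates > 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise EvaluationError(
            f"{label} is zero at nonzero count (row {int(rows[i])}, "
            f"column {int(cols[i])}): objective is infinite"
        )
    return rates, vals


def _check_shapes(X: CountMatrix, R, C) -> tuple[np.ndarray, np.ndarray]:
    R = np.asarray(R, dtype=float)
    C = np.asarray(C, dtype=float)
    if R.ndim != 2 or C.ndim != 2 or R.shape[0] != X.n or C.shape[0] != X.m:
        raise ValueError(
            f"factor shapes {R.shape}, {C.shape} incompatible with "
            f"{X.n}x{X.m} counts"
        )
    if R.shape[1] != C.shape[1]:
        raise ValueError("factor matrices must share the rank dimension K")
    return R, C


# ----------------------------------------------------------------------
# objectives (optimization convention, constants dropped)


def pnmf_objective(X, H, W) -> float:
    """Poisson NMF objective l(X; H, W) = sum_ij lambda_ij - x_ij log lambda_ij.

    The linear term is computed as ``colsums(H) . colsums(W)``; logarithms
    only at stored nonzeros.
    """
    X = _as_count_matrix(X)
    H, W = _check_shapes(X, H, W)
    lam, vals = _rates_at_nonzeros(X, H, W, "lambda_ij")
    return float(H.sum(axis=0) @ W.sum(axis=0) - vals @ np.log(lam))


def mtm_objective(X, L, F) -> float:
    """Topic-model objective phi(X; L, F) = -sum_ij x_ij log (L F^T)_ij."""
    X = _as_count_matrix(X)
    L, F = _check_shapes(X, L, F)
    pi, vals = _rates_at_nonzeros(X, L, F, "pi_ij")
    return float(-(vals @ np.log(pi)))


def augmented_objective(X, L, F, s) -> float:
    """phi(X; L, F) + psi(X; s) with psi = sum_i s_i - t_i log s_i.

    psi is uniquely minimized at s = t (the observed row sums), which is why
    the document scales drop out of topic-model maximum likelihood.
    """
    X = _as_count_matrix(X)
    s = np.asarray(s, dtype=float).ravel()
    if s.shape[0] != X.n:
        raise ValueError(f"s has length {s.shape[0]}, expected {X.n}")
    if not np.all(s > 0):
        raise ValueError("document scales s must be strictly positive")
    t = X.row_sums
    return mtm_objective(X, L, F) + float(np.sum(s) - t @ np.log(s))


# ----------------------------------------------------------------------
# full log-likelihoods (constants included)


def pnmf_loglik(X, H, W) -> float:
    """Poisson log-likelihood over all n*m cells, constants included.

    Zero-count cells contribute -lambda_ij, aggregated through column sums;
    the log x! constants are summed over nonzeros only (log 0! = 0).
    """
    X = _as_count_matrix(X)
    H, W = _check_shapes(X, H, W)
    vals = X.triplets()[2]
    return float(-pnmf_objective(X, H, W) - gammaln(vals + 1).sum())


def mtm_loglik(X, L, F) -> float:
    """Multinomial log-likelihood per row, multinomial coefficients included."""
    X = _as_count_matrix(X)
    L, F = _check_shapes(X, L, F)
    vals = X.triplets()[2]
    t = X.row_sums
    log_coef = float(gammaln(t + 1).sum() - gammaln(vals + 1).sum())
    return log_coef - mtm_objective(X, L, F)


def lemma_identity_gap(X, H, W) -> float:
    """Residual of the exact Poisson = multinomial x Poisson(t; s) identity.

    With (L, F, s, u) the reparameterization of (H, W), the Poisson NMF
    likelihood factors as the multinomial topic-model likelihood times the
    Poisson likelihood of the row totals t_i at rates s_i. Returns

        pnmf_loglik - mtm_loglik - sum_i log Pois(t_i; s_i),

    which is zero up to floating-point error for any valid (H, W).
    """
    X = _as_count_matrix(X)
    H, W = _check_shapes(X, H, W)
    L, F, s, _ = pnmf_to_mtm(H, W)
    t = X.row_sums
    log_pois_t = float(np.sum(t * np.log(s) - s - gammaln(t + 1)))
    return pnmf_loglik(X, H, W) - mtm_loglik(X, L, F) - log_pois_t


# ----------------------------------------------------------------------
# penalized objectives (MAP estimation)


def _dirichlet_penalty(M: np.ndarray, a: np.ndarray, label: str) -> float:
    active = a > 1
    if not active.any():
        return 0.0
    if np.any(M[active] <= 0):
        j, k = np.argwhere(active & (M <= 0))[0]
        raise EvaluationError(
            f"{label}[{int(j)},{int(k)}] = 0 with shape a > 1: penalty is infinite"
        )
    return float(-np.sum((a[active] - 1) * np.log(M[active])))


def penalized_pnmf_objective(X, H, W, pen: PenaltyParams) -> float:
    """l(X; H, W) - sum (a_jk - 1) log w_jk + sum b_k w_jk (gamma-prior MAP)."""
    X = _as_count_matrix(X)
    H, W = _check_shapes(X, H, W)
    m, K = W.shape
    a = pen.shape_matrix(m, K)
    b = pen.rate_vector(K)
    rho = _dirichlet_penalty(W, a, "W") + float(np.sum(b * W.sum(axis=0)))
    return pnmf_objective(X, H, W) + rho


def penalized_mtm_objective(X, L, F, pen: PenaltyParams) -> float:
    """phi(X; L, F) - sum (a_jk - 1) log f_jk (Dirichlet-prior MAP)."""
    X = _as_count_matrix(X)
    L, F = _check_shapes(X, L, F)
    m, K = F.shape
    a = pen.shape_matrix(m, K)
    return mtm_objective(X, L, F) + _dirichlet_penalty(F, a, "F")
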