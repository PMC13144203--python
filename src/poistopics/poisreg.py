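"""Non-negative additive Poisson regression: the inner kernel of the fitter.

Each block update of the alternating scheme splits into independent
K-dimensional subproblems

    minimize  sum_i mu_i - y_i log mu_i,   mu_i = sum_k a_ik b_k,   b >= 0,

one per row (or column) of the count matrix. Two solvers are provided:

* EM (the classic Richardson-Lucy / Shepp-Vardi updates), which multiplies
  each coefficient by a responsibility-weighted ratio and never increases
  the objective; and
* cyclic coordinate descent with a full feasible Newton step per coordinate
  (no line search), which is not monotone per sweep but converges much
  faster in practice; the outer driver's best-iterate tracking provides the
  safety net.

Both solvers touch only the rows with y_i > 0 beyond precomputed column sums
of the design, which is what makes whole-matrix updates cost O(nnz).
Batched versions run every subproblem of a block in lock-step over the
sparse nonzeros; they are arithmetically identical to solving subproblems
one at a time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp

from .objectives import EvaluationError, PenaltyParams

__all__ = [
    "EPS_FLOOR",
    "EPS_KKT",
    "SolverError",
    "PoisRegProblem",
    "PoisRegFit",
    "poisreg_neg_loglik",
    "em_step",
    "cd_sweep",
    "kkt_residual",
    "fit_pois_reg",
    "BlockProblem",
    "em_block",
    "cd_block",
]

#: hard floor applied to every fitted parameter after each update; prevents
#: log(0) and division by zero while perturbing objectives only at ~1e-15
EPS_FLOOR = 1e-15

#: coefficients above this are treated as interior when certifying optimality
EPS_KKT = 1e-10

#: curvature below this is treated as exactly zero (boundary analysis applies)
QTINY = 1e-300


class SolverError(RuntimeError):
    """An inner solver encountered an invalid state."""


@dataclass
class PoisRegProblem:
    """One additive Poisson regression subproblem.

    A is the fixed n x K design (the other factor block), y the length-n
    response (one row or column of the counts), b the current non-negative
    coefficient vector, and mu = A b the fitted means.
    """

    A: np.ndarray
    y: np.ndarray
    b: np.ndarray
    mu: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.b = np.asarray(self.b, dtype=float).ravel().copy()
        if self.A.ndim != 2 or self.A.shape[0] != self.y.shape[0]:
            raise ValueError("design and response shapes are inconsistent")
        if self.A.shape[1] != self.b.shape[0]:
            raise ValueError("coefficient length must match design columns")
        if np.any(self.b < 0) or np.any(self.A < 0) or np.any(self.y < 0):
            raise ValueError("A, y and b must be non-negative")
        self.refresh_mu()

    def refresh_mu(self) -> None:
        self.mu = self.A @ self.b


def _pen_terms(pen: PenaltyParams | None, K: int) -> tuple[np.ndarray, np.ndarray] | None:
    """Penalty shape row (length K, for one subproblem) and rate vector."""
    if pen is None or pen.is_null:
        return None
    a = np.asarray(pen.dirichlet_a, dtype=float)
    if a.ndim > 1:
        raise ValueError(
            "per-term penalty matrices apply to whole blocks; pass the "
            "relevant row (length-K shapes) for a single subproblem"
        )
    return np.broadcast_to(a, (K,)).copy(), pen.rate_vector(K)


def poisreg_neg_loglik(p: PoisRegProblem) -> float:
    """sum_i mu_i - y_i log mu_i (constants dropped)."""
    pos = p.y > 0
    bad = pos & (p.mu <= 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise EvaluationError(f"mu = 0 at positive count (observation {i})")
    return float(p.mu.sum() - p.y[pos] @ np.log(p.mu[pos]))


def em_step(p: PoisRegProblem, pen: PenaltyParams | None = None) -> np.ndarray:
    """One EM update of every coefficient; returns (and stores) the new b.

    Unpenalized, this is b_k <- (sum_i y_i a_ik b_k / mu_i) / (sum_i a_ik);
    the penalty adds (a_k - 1) to the numerator and b_k^pen to the
    denominator. The unpenalized update never increases the objective.
    """
    pos = p.y > 0
    if np.any(p.mu[pos] <= 0):
        raise SolverError("mu = 0 at a positive count; cannot take EM step")
    r = np.zeros_like(p.y)
    r[pos] = p.y[pos] / p.mu[pos]
    num = p.b * (p.A.T @ r)
    den = p.A.sum(axis=0)
    terms = _pen_terms(pen, p.b.shape[0])
    if terms is not None:
        a_row, b_rate = terms
        num = num + (a_row - 1.0)
        den = den + b_rate
    # a zero design column gives 0/0: no support for that topic, floor it
    ratio = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    p.b = np.maximum(EPS_FLOOR, ratio)
    p.refresh_mu()
    return p.b


def cd_sweep(p: PoisRegProblem, pen: PenaltyParams | None = None) -> np.ndarray:
    """One cyclic coordinate-descent sweep (full feasible Newton steps).

    For k = 1..K in order: gradient g_k = sum_i a_ik (1 - y_i / mu_i),
    curvature q_k = sum_i y_i a_ik^2 / mu_i^2, then
    b_k <- max(EPS_FLOOR, b_k - g_k / q_k), with mu updated incrementally.
    Zero curvature means the likelihood is linear in b_k: if the slope is
    positive the optimum is at the boundary (b_k = floor); otherwise the
    coordinate is left unchanged with a warning.
    """
    terms = _pen_terms(pen, p.b.shape[0])
    colsA = p.A.sum(axis=0)
    pos = p.y > 0
    for k in range(p.A.shape[1]):
        mu_pos = p.mu[pos]
        if np.any(mu_pos <= 0):
            raise SolverError("mu = 0 at a positive count during CD sweep")
        ak = p.A[:, k]
        g = colsA[k] - float(ak[pos] @ (p.y[pos] / mu_pos))
        q = float((p.y[pos] * ak[pos] ** 2) @ (1.0 / mu_pos**2))
        if terms is not None:
            a_row, b_rate = terms
            g += b_rate[k] - (a_row[k] - 1.0) / p.b[k]
            q += (a_row[k] - 1.0) / p.b[k] ** 2
        if q <= QTINY:
            if g > 0:
                new_bk = EPS_FLOOR
            else:
                warnings.warn(
                    f"coordinate {k}: zero curvature with non-positive "
                    "gradient; leaving coefficient unchanged",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
        else:
            new_bk = max(EPS_FLOOR, p.b[k] - g / q)
        delta = new_bk - p.b[k]
        if delta != 0.0:
            p.mu = p.mu + ak * delta
            p.b[k] = new_bk
    return p.b


def kkt_residual(
    A, y, b, pen: PenaltyParams | None = None, eps_active: float = EPS_KKT
) -> float:
    """First-order optimality residual for the bound-constrained subproblem.

    r = max_k |g_k| over coordinates with b_k > eps_active, and
    max(0, -g_k) over coordinates at the bound; zero at a constrained
    stationary point.
    """
    p = PoisRegProblem(A=A, y=y, b=b)
    pos = p.y > 0
    if np.any(p.mu[pos] <= 0):
        return np.inf
    r = np.zeros_like(p.y)
    r[pos] = p.y[pos] / p.mu[pos]
    g = p.A.sum(axis=0) - p.A.T @ r
    terms = _pen_terms(pen, p.b.shape[0])
    if terms is not None:
        a_row, b_rate = terms
        g = g + b_rate - (a_row - 1.0) / p.b
    interior = p.b > eps_active
    res = np.where(interior, np.abs(g), np.maximum(0.0, -g))
    return float(res.max()) if res.size else 0.0


class PoisRegFit(NamedTuple):
    """Solution of one subproblem: coefficients plus the KKT certificate."""

    b: np.ndarray
    kkt: float
    n_iter: int


def fit_pois_reg(
    A,
    y,
    b0,
    method: str = "em",
    num_iter: int = 4,
    pen: PenaltyParams | None = None,
) -> PoisRegFit:
    """Run ``num_iter`` EM steps or CD sweeps from b0; returns b with its
    KKT residual attached."""
    if num_iter < 1:
        raise ValueError("num_iter must be >= 1")
    if method not in {"em", "cd"}:
        raise ValueError(f"unknown method {method!r}")
    p = PoisRegProblem(A=A, y=y, b=b0)
    step = em_step if method == "em" else cd_sweep
    for _ in range(num_iter):
        step(p, pen)
    return PoisRegFit(b=p.b, kkt=kkt_residual(A, y, p.b, pen), n_iter=num_iter)


# ----------------------------------------------------------------------
# batched block solvers


@dataclass
class BlockProblem:
    """All subproblems of one block, in sparse column-major (CSC) layout.

    ``rows`` index into the shared design matrix, ``cols`` identify the
    subproblem, ``vals`` are the positive counts. Within a subproblem the
    nonzeros appear in ascending row order, so results do not depend on how
    subproblems are interleaved.
    """

    rows: np.ndarray
    cols: np.ndarray
    vals: np.ndarray
    n_sub: int

    @classmethod
    def from_sparse_columns(cls, mat) -> "BlockProblem":
        """Build from a sparse matrix whose columns are the responses."""
        csc = sp.csc_matrix(mat)
        csc.sum_duplicates()
        csc.eliminate_zeros()
        n_per_col = np.diff(csc.indptr)
        return cls(
            rows=csc.indices.astype(np.int64),
            cols=np.repeat(np.arange(csc.shape[1], dtype=np.int64), n_per_col),
            vals=np.asarray(csc.data, dtype=float),
            n_sub=csc.shape[1],
        )


def _mu_at_nonzeros(Ar: np.ndarray, B: np.ndarray, blk: BlockProblem) -> np.ndarray:
    mu = np.einsum("nk,nk->n", Ar, B[blk.cols])
    if mu.size and not np.all(mu > 0):
        i = int(np.flatnonzero(~(mu > 0))[0])
        raise SolverError(
            f"mu = 0 at positive count (design row {int(blk.rows[i])}, "
            f"subproblem {int(blk.cols[i])})"
        )
    return mu


def _colsum_per_sub(weights: np.ndarray, blk: BlockProblem) -> np.ndarray:
    return np.bincount(blk.cols, weights=weights, minlength=blk.n_sub)


def em_block(
    A: np.ndarray,
    blk: BlockProblem,
    B: np.ndarray,
    n_iter: int,
    pen: PenaltyParams | None = None,
) -> np.ndarray:
    """EM steps for every subproblem of a block, in lock-step."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float).copy()
    p, K = B.shape
    colsA = A.sum(axis=0)
    Ar = A[blk.rows]
    a_pen = b_pen = None
    if pen is not None and not pen.is_null:
        a_pen = pen.shape_matrix(p, K)
        b_pen = pen.rate_vector(K)
    for _ in range(n_iter):
        mu = _mu_at_nonzeros(Ar, B, blk)
        r = blk.vals / mu
        num = B * np.column_stack(
            [_colsum_per_sub(Ar[:, k] * r, blk) for k in range(K)]
        )
        den = colsA
        if a_pen is not None:
            num = num + (a_pen - 1.0)
            den = colsA + b_pen
        den = np.broadcast_to(den, num.shape)
        ratio = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        B = np.maximum(EPS_FLOOR, ratio)
    return B


def cd_block(
    A: np.ndarray,
    blk: BlockProblem,
    B: np.ndarray,
    n_sweeps: int,
    pen: PenaltyParams | None = None,
) -> np.ndarray:
    """CD sweeps for every subproblem of a block, in lock-step."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float).copy()
    p, K = B.shape
    colsA = A.sum(axis=0)
    Ar = A[blk.rows]
    a_pen = b_pen = None
    if pen is not None and not pen.is_null:
        a_pen = pen.shape_matrix(p, K)
        b_pen = pen.rate_vector(K)
    mu = _mu_at_nonzeros(Ar, B, blk)
    for _ in range(n_sweeps):
        for k in range(K):
            ak = Ar[:, k]
            ratio = ak / mu
            g = colsA[k] - _colsum_per_sub(ratio * blk.vals, blk)
            q = _colsum_per_sub(blk.vals * ratio**2, blk)
            bk = B[:, k]
            if a_pen is not None:
                g = g + b_pen[k] - (a_pen[:, k] - 1.0) / bk
                q = q + (a_pen[:, k] - 1.0) / bk**2
            qsafe = np.where(q > QTINY, q, 1.0)
            newton = np.maximum(EPS_FLOOR, bk - g / qsafe)
            # zero curvature: boundary if the objective slopes upward, else hold
            new_bk = np.where(q > QTINY, newton, np.where(g > 0, EPS_FLOOR, bk))
            delta = new_bk - bk
            if np.any(delta != 0.0):
                mu = mu + ak * delta[blk.cols]
                B[:, k] = new_bk
        if np.any(mu <= 0):
            raise SolverError("mu became non-positive during CD sweep")
    return B
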