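"""Alternating Poisson regression for Poisson NMF, statsmodels-style.

:class:`PoissonNMF` is the model object (counts plus rank); ``.fit()`` runs
the block-coordinate scheme -- alternately re-solving all row subproblems
(loadings H, design W) and all column subproblems (factors W, design H) with
either EM or coordinate-descent inner updates -- and returns a
:class:`PoissonNMFResults` carrying the best-objective iterate, the progress
trace and diagnostics. ``.to_topic_model()`` applies the exact change of
variables to obtain the multinomial topic-model parameterization, which by
the likelihood equivalence is a topic-model maximum-likelihood estimate
whenever the Poisson NMF solution is one.

An optional momentum-like extrapolation accelerates the block updates: each
outer update is taken from an extrapolated point, the step size grows while
extrapolated updates keep improving the objective and shrinks (with a
restart from the best iterate) when they fail.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import objectives as obj
from .data import CountMatrix, DataError, validate_counts
from .objectives import PenaltyParams
from .poisreg import (
    EPS_FLOOR,
    BlockProblem,
    SolverError,
    cd_block,
    em_block,
    kkt_residual,
)
from .reparam import pnmf_to_mtm

__all__ = [
    "ProgressRecord",
    "FitConfig",
    "PoissonNMF",
    "PoissonNMFResults",
    "TopicModelResults",
    "fit_pnmf",
    "fit_topic_model",
    "update_block",
    "multiplicative_update",
    "extrapolated_iterate",
    "progress_report",
]


@dataclass
class ProgressRecord:
    outer_iteration: int
    objective: float
    extrapolated: bool
    beta: float


@dataclass
class FitConfig:
    """Solver configuration.

    K : rank (number of topics), >= 2.
    method : "em" or "cd" inner solver.
    num_outer : outer iterations (each updates the H block then the W block).
    inner_iter : EM steps / CD sweeps per subproblem per block update.
    extrapolate / extrapolate_start : momentum acceleration, activated at the
        given outer iteration.
    beta0, beta_growth, beta_bar_growth, beta_shrink : extrapolation step
        size controls (initial step, growth on success, cap growth, shrink
        on failure).
    init : "random" (scale-matched uniform draws polished by
        ``init_prefit_iters`` EM updates) or "given" (explicit H0, W0).
    pen : optional penalty (applied to W-block subproblems only; uniform
        prior on H).
    tol_rel_obj : stop early when the relative objective change falls below
        this (0 disables; the iteration cap is primary).
    """

    K: int
    method: str = "cd"
    num_outer: int = 100
    inner_iter: int = 4
    extrapolate: bool = False
    extrapolate_start: int = 50
    beta0: float = 0.5
    beta_growth: float = 1.05
    beta_bar_growth: float = 1.01
    beta_shrink: float = 1.5
    init: str = "random"
    init_prefit_iters: int = 10
    seed: int = 0
    pen: PenaltyParams | None = None
    tol_rel_obj: float = 1e-8

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.method not in {"em", "cd"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.num_outer < 1 or self.inner_iter < 1:
            raise ValueError("num_outer and inner_iter must be >= 1")
        if not (0 < self.beta0 < 1):
            raise ValueError("beta0 must lie in (0, 1)")
        if self.init not in {"random", "given"}:
            raise ValueError(f"unknown init {self.init!r}")


def _config_from_dict(d):
    if d is None:
        return None
    d = dict(d)
    pen = d.get("pen")
    if pen is not None:
        d["pen"] = PenaltyParams(
            dirichlet_a=np.asarray(pen["dirichlet_a"])
            if isinstance(pen["dirichlet_a"], list)
            else pen["dirichlet_a"],
            gamma_b=np.asarray(pen["gamma_b"])
            if isinstance(pen["gamma_b"], list)
            else pen["gamma_b"],
        )
    return FitConfig(**d)


# ----------------------------------------------------------------------
# free functions of the algorithm


def extrapolated_iterate(current, previous, beta: float) -> np.ndarray:
    """max(EPS_FLOOR, current + beta * (current - previous)) elementwise."""
    current = np.asarray(current, dtype=float)
    previous = np.asarray(previous, dtype=float)
    return np.maximum(EPS_FLOOR, current + beta * (current - previous))


def update_block(
    X,
    fixed_block,
    target_block,
    method: str = "cd",
    inner_iter: int = 4,
    pen: PenaltyParams | None = None,
    block: str | None = None,
) -> np.ndarray:
    """Re-solve every independent subproblem of one factor block.

    Updating the loadings H uses the rows of X with design W; updating the
    factors W uses the columns of X with design H. The subproblems are
    independent, so the result does not depend on the order in which they
    are processed.

    ``block`` ("loadings" or "factors") is only needed when X is square and
    the orientation cannot be inferred from the shapes.
    """
    X = X if isinstance(X, CountMatrix) else CountMatrix(X)
    fixed = np.asarray(fixed_block, dtype=float)
    target = np.asarray(target_block, dtype=float)
    if block is None:
        is_loadings = target.shape[0] == X.n and fixed.shape[0] == X.m
        is_factors = target.shape[0] == X.m and fixed.shape[0] == X.n
        if is_loadings and is_factors:
            raise ValueError("square X: specify block='loadings' or 'factors'")
        if not (is_loadings or is_factors):
            raise ValueError("block shapes do not match the count matrix")
        block = "loadings" if is_loadings else "factors"
    if block == "loadings":
        blk = BlockProblem.from_sparse_columns(X.csr.T)
    elif block == "factors":
        blk = BlockProblem.from_sparse_columns(X.csc)
    else:
        raise ValueError(f"unknown block {block!r}")
    solver = em_block if method == "em" else cd_block
    if method not in {"em", "cd"}:
        raise ValueError(f"unknown method {method!r}")
    return solver(fixed, blk, target, inner_iter, pen)


def multiplicative_update(X, H, W) -> tuple[np.ndarray, np.ndarray]:
    """Classic multiplicative (Lee-Seung) updates for the Poisson objective.

    h_ik <- h_ik (sum_j x_ij w_jk / lambda_ij) / (sum_j w_jk) with the
    current W, then the analogous update of W with the *updated* H. This is
    the reference implementation used to pin down the EM block update
    (one inner EM step is exactly one multiplicative update); it is not the
    production path.
    """
    import scipy.sparse as sp

    X = X if isinstance(X, CountMatrix) else CountMatrix(X)
    H = np.asarray(H, dtype=float)
    W = np.asarray(W, dtype=float)
    rows, cols, vals = X.triplets()

    def _ratio(Hc, Wc):
        lam = np.einsum("nk,nk->n", Hc[rows], Wc[cols])
        if np.any(lam <= 0):
            i = int(np.flatnonzero(lam <= 0)[0])
            raise obj.EvaluationError(
                f"lambda = 0 at nonzero count (row {int(rows[i])}, "
                f"column {int(cols[i])})"
            )
        return sp.csr_matrix((vals / lam, (rows, cols)), shape=X.shape)

    R = _ratio(H, W)
    H_new = H * np.asarray(R @ W) / W.sum(axis=0)
    R = _ratio(H_new, W)
    W_new = W * np.asarray(R.T @ H_new) / H_new.sum(axis=0)
    return H_new, W_new


def progress_report(fit) -> pd.DataFrame:
    """Flat progress table: iteration, objective, gap to the best objective
    in the trace, extrapolation state."""
    trace = fit.trace if hasattr(fit, "trace") else fit
    objectives = np.array([r.objective for r in trace], dtype=float)
    best = objectives.min() if objectives.size else np.nan
    return pd.DataFrame(
        {
            "outer_iteration": [r.outer_iteration for r in trace],
            "objective": objectives,
            "delta_best": objectives - best,
            "extrapolated": [r.extrapolated for r in trace],
            "beta": [r.beta for r in trace],
        }
    )


# ----------------------------------------------------------------------
# model / results objects


class PoissonNMF:
    """Poisson NMF model of a count matrix: x_ij ~ Pois((H W^T)_ij).

    Parameters
    ----------
    X : CountMatrix, array-like, or scipy sparse matrix
        Non-negative integer counts; all-zero rows or columns are rejected
        (filter them first, e.g. with :func:`poistopics.data.drop_empty`).
    K : int
        Rank / number of topics, >= 2.
    pen : PenaltyParams, optional
        Equivalence-preserving penalty on W (MAP with gamma priors).
    """

    def __init__(self, X, K: int, pen: PenaltyParams | None = None) -> None:
        self.X = X if isinstance(X, CountMatrix) else CountMatrix(X)
        problems = validate_counts(self.X)
        if problems:
            raise DataError(
                "count matrix has all-zero rows/columns; filter them before "
                "fitting: " + "; ".join(problems)
            )
        if K < 2:
            raise ValueError("K must be >= 2")
        self.K = int(K)
        self.pen = pen
        # CSC layouts of the two blocks' subproblems, built once
        self._blk_loadings = BlockProblem.from_sparse_columns(self.X.csr.T)
        self._blk_factors = BlockProblem.from_sparse_columns(self.X.csc)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, K: int, **kwargs) -> "PoissonNMF":
        """Build from a dense documents x terms DataFrame."""
        return cls(CountMatrix(df.to_numpy()), K, **kwargs)

    # -- pieces of the fit -------------------------------------------------

    def _outer_update(self, H, W, method: str, inner_iter: int):
        H = em_block(W, self._blk_loadings, H, inner_iter, None) \
            if method == "em" else cd_block(W, self._blk_loadings, H, inner_iter, None)
        W = em_block(H, self._blk_factors, W, inner_iter, self.pen) \
            if method == "em" else cd_block(H, self._blk_factors, W, inner_iter, self.pen)
        return H, W

    def _objective(self, H, W) -> float:
        value = obj.pnmf_objective(self.X, H, W)
        if self.pen is not None and not self.pen.is_null:
            value = obj.penalized_pnmf_objective(self.X, H, W, self.pen)
        return value

    def _initialize(self, cfg: FitConfig, H0, W0):
        if cfg.init == "given":
            if H0 is None or W0 is None:
                raise ValueError("init='given' requires H0 and W0")
            H = np.maximum(EPS_FLOOR, np.asarray(H0, dtype=float).copy())
            W = np.maximum(EPS_FLOOR, np.asarray(W0, dtype=float).copy())
            return H, W
        rng = np.random.default_rng(cfg.seed)
        H = 1.0 - rng.random((self.X.n, self.K))  # uniform on (0, 1]
        W = 1.0 - rng.random((self.X.m, self.K))
        # scale-matched start: mean(H W^T) = mean(X)
        mean_model = float(H.sum(axis=0) @ W.sum(axis=0)) / (self.X.n * self.X.m)
        mean_data = self.X.row_sums.sum() / (self.X.n * self.X.m)
        c = np.sqrt(mean_data / mean_model)
        H *= c
        W *= c
        # polish with EM outer updates (inner_iter=1: multiplicative updates)
        for _ in range(cfg.init_prefit_iters):
            H, W = self._outer_update(H, W, "em", 1)
        return H, W

    def fit(self, config: FitConfig | None = None, H0=None, W0=None, **kwargs):
        """Run the alternating scheme and return :class:`PoissonNMFResults`.

        Either pass a full :class:`FitConfig` or keyword overrides of its
        fields (``method=``, ``num_outer=``, ``seed=``, ...). ``H0``/``W0``
        start the fit at explicit matrices (``init="given"``).
        """
        if config is None:
            if H0 is not None or W0 is not None:
                kwargs.setdefault("init", "given")
            config = FitConfig(K=self.K, **kwargs)
        elif kwargs:
            config = dataclasses.replace(config, **kwargs)
        if config.K != self.K:
            raise ValueError("config.K disagrees with the model's K")
        cfg = config
        if cfg.pen is not None and self.pen is None:
            self.pen = cfg.pen

        H, W = self._initialize(cfg, H0, W0)
        f_cur = self._objective(H, W)
        H_best, W_best, f_best = H, W, f_cur
        H_prev, W_prev = H, W  # previous accepted iterate (momentum anchor)
        beta = cfg.beta0
        beta_bar = 1.0
        trace: list[ProgressRecord] = []
        for it in range(1, cfg.num_outer + 1):
            use_extra = cfg.extrapolate and it >= cfg.extrapolate_start
            if use_extra:
                He = extrapolated_iterate(H, H_prev, beta)
                We = extrapolated_iterate(W, W_prev, beta)
            else:
                He, We = H, W
            Hn, Wn = self._outer_update(He, We, cfg.method, cfg.inner_iter)
            f_new = self._objective(Hn, Wn)
            if not np.isfinite(f_new):
                raise SolverError(f"non-finite objective at outer iteration {it}")
            f_old = f_cur
            accepted = True
            if use_extra:
                if f_new < f_cur:  # extrapolated update accepted
                    H_prev, W_prev = H, W
                    H, W, f_cur = Hn, Wn, f_new
                    beta = min(beta_bar, cfg.beta_growth * beta)
                    beta_bar = min(1.0, cfg.beta_bar_growth * beta_bar)
                else:  # reject: restart from the best iterate, damp the step
                    accepted = False
                    H, W = H_best, W_best
                    H_prev, W_prev = H_best, W_best
                    f_cur = f_best
                    beta_bar = beta
                    beta = beta / cfg.beta_shrink
            else:
                H_prev, W_prev = H, W
                H, W, f_cur = Hn, Wn, f_new
            if f_new < f_best:
                H_best, W_best, f_best = Hn, Wn, f_new
            trace.append(
                ProgressRecord(
                    outer_iteration=it,
                    objective=f_cur,
                    extrapolated=use_extra,
                    beta=beta if use_extra else 0.0,
                )
            )
            if cfg.tol_rel_obj > 0 and it > 1 and accepted:
                if abs(f_old - f_cur) <= cfg.tol_rel_obj * (1.0 + abs(f_cur)):
                    break
        return PoissonNMFResults(
            H=H_best,
            W=W_best,
            objective=f_best,
            trace=trace,
            config=cfg,
            model=self,
        )


class PoissonNMFResults:
    """Fitted Poisson NMF: best-objective iterate, trace and diagnostics."""

    def __init__(self, H, W, objective, trace, config=None, model=None) -> None:
        self.H = np.asarray(H, dtype=float)
        self.W = np.asarray(W, dtype=float)
        self.objective = objective
        self.trace = list(trace)
        self.config = config
        self.model = model

    @property
    def K(self) -> int:
        return self.H.shape[1]

    def _require_model(self) -> PoissonNMF:
        if self.model is None:
            raise ValueError(
                "this results object has no attached data (e.g. it was read "
                "from disk); rebuild it through PoissonNMF(X, K)"
            )
        return self.model

    @property
    def loglik(self) -> float:
        """Poisson log-likelihood at the fit, constants included."""
        return obj.pnmf_loglik(self._require_model().X, self.H, self.W)

    def kkt_residuals(self) -> dict[str, np.ndarray]:
        """Per-subproblem first-order optimality residuals for both blocks."""
        model = self._require_model()
        Xd = model.X.toarray()
        r_H = np.array(
            [kkt_residual(self.W, Xd[i], self.H[i]) for i in range(model.X.n)]
        )
        r_W = np.array(
            [
                kkt_residual(self.H, Xd[:, j], self.W[j], _pen_row(model.pen, j))
                for j in range(model.X.m)
            ]
        )
        return {"loadings": r_H, "factors": r_W}

    def to_topic_model(self) -> "TopicModelResults":
        """Exact reparameterization to (L, F, s, u)."""
        L, F, s, u = pnmf_to_mtm(self.H, self.W)
        return TopicModelResults(L=L, F=F, s=s, u=u, pnmf=self, model=self.model)

    def progress(self) -> pd.DataFrame:
        return progress_report(self)

    def save(self, path) -> None:
        from .io import write_fit

        write_fit(self, path)

    def summary(self) -> str:
        model = self.model
        lines = ["Poisson NMF fit", "=" * 40]
        if model is not None:
            lines.append(
                f"data:            {model.X.n} x {model.X.m} counts, "
                f"nnz = {model.X.nnz}"
            )
        cfg = self.config
        if cfg is not None:
            lines.append(
                f"solver:          {cfg.method}"
                + (", extrapolated" if cfg.extrapolate else "")
            )
            lines.append(
                f"outer iters:     {len(self.trace)} (inner {cfg.inner_iter})"
            )
        lines.append(f"topics (K):      {self.K}")
        lines.append(f"objective:       {self.objective:.10g}")
        if model is not None:
            lines.append(f"Poisson loglik:  {self.loglik:.10g}")
            tm = self.to_topic_model()
            lines.append(f"topic loglik:    {tm.loglik:.10g}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PoissonNMFResults(K={self.K}, objective={self.objective})"


def _pen_row(pen: PenaltyParams | None, j: int) -> PenaltyParams | None:
    """Penalty restricted to subproblem j (one row of the shape matrix)."""
    if pen is None or pen.is_null:
        return None
    a = np.asarray(pen.dirichlet_a)
    return PenaltyParams(
        dirichlet_a=a[j] if a.ndim == 2 else pen.dirichlet_a,
        gamma_b=pen.gamma_b,
    )


class TopicModelResults:
    """Multinomial topic-model parameterization of a Poisson NMF fit.

    L rows (topic proportions per document) sum to 1; F columns (term
    distributions per topic) sum to 1; s are document scales (equal to the
    row sums of H W^T, and to the observed row totals t at an exact MLE);
    u are the topic scales absorbed out of W (retained for invertibility).
    """

    def __init__(self, L, F, s, u, pnmf=None, model=None) -> None:
        self.L = np.asarray(L, dtype=float)
        self.F = np.asarray(F, dtype=float)
        self.s = np.asarray(s, dtype=float).ravel()
        self.u = np.asarray(u, dtype=float).ravel()
        self.pnmf = pnmf
        self.model = model

    @property
    def K(self) -> int:
        return self.L.shape[1]

    def _require_model(self) -> PoissonNMF:
        if self.model is None:
            raise ValueError("this results object has no attached data")
        return self.model

    @property
    def phi(self) -> float:
        """Topic-model objective -sum x_ij log (L F^T)_ij."""
        return obj.mtm_objective(self._require_model().X, self.L, self.F)

    @property
    def loglik(self) -> float:
        """Multinomial log-likelihood, multinomial coefficients included."""
        return obj.mtm_loglik(self._require_model().X, self.L, self.F)

    def save(self, path) -> None:
        from .io import write_fit

        write_fit(self, path)

    def summary(self) -> str:
        lines = ["Multinomial topic model fit", "=" * 40]
        model = self.model
        if model is not None:
            lines.append(f"data:            {model.X.n} x {model.X.m} counts")
        lines.append(f"topics (K):      {self.K}")
        if model is not None:
            lines.append(f"objective phi:   {self.phi:.10g}")
            lines.append(f"multinom loglik: {self.loglik:.10g}")
            t = model.X.row_sums
            rel = np.max(np.abs(self.s - t) / t)
            lines.append(f"max |s-t|/t:     {rel:.3g}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TopicModelResults(K={self.K})"


# ----------------------------------------------------------------------
# functional wrappers


def fit_pnmf(X, config: FitConfig) -> PoissonNMFResults:
    """Fit the Poisson NMF model of X under ``config``."""
    model = PoissonNMF(X, config.K, pen=config.pen)
    return model.fit(config=config)


def fit_topic_model(X, config: FitConfig) -> TopicModelResults:
    """Fit Poisson NMF, then reparameterize to the topic model."""
    return fit_pnmf(X, config).to_topic_model()
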