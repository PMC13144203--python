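# Methods

## Models

`poistopics` fits two closely related models of an n × m matrix **X** of
non-negative integer counts (documents × terms, cells × genes):

* **Poisson NMF.** x_ij ~ Pois(λ_ij) with λ = **H W**ᵀ, **H** ∈ R₊^{n×K}
  (loadings), **W** ∈ R₊^{m×K} (factors). Maximum likelihood minimizes

      ℓ(X; H, W) = Σ_ij λ_ij − x_ij log λ_ij,   H, W ≥ 0.

* **Multinomial topic model.** Each row x_i ~ Multin(t_i; π_i) with
  **Π** = **L F**ᵀ, rows of **L** on the simplex (topic proportions) and
  columns of **F** on the simplex (topic term distributions); t_i is the
  row total. Maximum likelihood minimizes φ(X; L, F) = −Σ x_ij log π_ij
  subject to the sum-to-one constraints.

The two are linked by an exact change of variables: normalizing the columns
of **W** yields (F, u); normalizing the rows of **H** diag(u) yields (L, s);
then λ_ij = s_i π_ij identically, and the Poisson likelihood factors as the
multinomial likelihood times Π_i Pois(t_i; s_i). Consequently a Poisson NMF
MLE maps to a topic-model MLE, and at an exact MLE s equals the observed row
totals t. This is why the package optimizes the *unconstrained* (bound-only)
Poisson problem and converts afterwards: the simplex constraints that make
topic-model optimization awkward never appear.

All objectives are evaluated in O(nnz(X) + (n+m)K): the linear term Σ λ_ij
collapses to colsums(**H**)·colsums(**W**), and logarithms are taken only at
stored nonzeros. Full log-likelihoods (with log x! and multinomial
coefficients, via log-gamma) are separate functions so the factorization
identity can be verified with no constants dropped; the identity holds to
~1e-15 relative in the tests.

## Optimization

The driver is block coordinate descent: alternately re-solve for **H** with
**W** fixed and for **W** with **H** fixed. Each block separates into
independent K-dimensional **additive Poisson regressions**

    minimize_b≥0  Σ_i μ_i − y_i log μ_i,   μ = A b,

one per row/column of X. Two inner solvers are implemented:

* **EM** — the Richardson-Lucy / Shepp-Vardi multiplicative update
  b_k ← b_k (Σ_i y_i a_ik / μ_i) / (Σ_i a_ik). With one inner step per
  block update this reproduces, exactly and elementwise, the classic
  multiplicative NMF updates (a pinned test asserts bitwise-level
  agreement), and is therefore monotone in the objective.
* **CD** — cyclic coordinate descent with a full feasible Newton step per
  coordinate: b_k ← max(ε, b_k − g_k/q_k) with g_k = Σ a_ik(1 − y_i/μ_i),
  q_k = Σ y_i a_ik²/μ_i², μ updated incrementally. No line search is used;
  individual sweeps may increase the objective, and the driver's
  best-iterate tracking (below) is the safety net. CD converges far faster
  than EM near solutions and is the default.

Subproblems within a block are independent; the implementation runs them in
lock-step over the sparse nonzeros (per-subproblem `bincount` reductions),
which is arithmetically identical to solving them one at a time and
invariant to subproblem ordering. Coordinates are visited in fixed ascending
order for determinism.

Optionally, a penalty −Σ(a_jk−1) log w_jk + Σ b_k w_jk on **W** (equivalent
to MAP estimation with gamma priors on **W**, or Dirichlet priors on the
columns of **F** after the change of variables, and a uniform prior on
**H**/**L**) enters both solvers through its exact gradient/curvature
contributions. The penalized Poisson and topic-model objectives differ by a
function of the topic scales u alone, so the equivalence is preserved along
the change of variables at fixed u.

### Extrapolation

A momentum-like acceleration can be activated at a chosen outer iteration
(default 50): updates are taken from the extrapolated point
max(ε, current + β(current − previous)). The step size adapts by
acceptance: if the objective decreased, the point is accepted and β grows
(β ← min(β̄, γβ), with the cap β̄ itself growing slowly toward 1); if not,
the run restarts from the best iterate seen and β shrinks (β̄ ← β,
β ← β/η). Defaults: β₀ = 0.5, γ = 1.05, γ̄ = 1.01, η = 1.5, β̄₀ = 1. The
exact constants are not critical — the acceptance rule makes the scheme
safe — and all are configurable.

### Initialization, stopping, numerics

* Random starts are elementwise uniform(0, 1], rescaled so mean(**H W**ᵀ)
  equals mean(X) (avoids absurd initial rates), then polished by a
  configurable number of EM outer updates (default 10) before the main
  method runs. Because the polish is deterministic given the seed, two fits
  with the same seed but different methods branch from the identical point,
  which is how the EM-vs-CD comparisons are run.
* The iteration cap `num_outer` is the primary stopping rule; a relative
  objective-change tolerance (default 1e-8, 0 disables) can stop earlier.
* Every fitted parameter is floored at ε = 1e-15 after each update. This
  prevents log(0)/division-by-zero while perturbing objectives only at the
  last floating-point digit.
* The returned fit is the best-objective iterate encountered, so the
  reported objective is non-increasing in the iteration budget for every
  configuration, including non-monotone CD and extrapolated runs.
* Degenerate inner cases: a topic with no support in the fixed block (zero
  design column) is driven to the floor; zero curvature with positive slope
  sends the coordinate to the boundary; zero curvature with non-positive
  slope leaves it unchanged with a warning.
* All-zero rows or columns of X are rejected at model construction (no
  meaningful estimate exists for them); `drop_empty` filters them and
  reports the retained indices.

Diagnostics on the results object include per-subproblem KKT residuals
(max |g_k| over interior coordinates, max(0, −g_k) at the bound), the
progress trace, and both models' log-likelihoods.

## Synthetic data

`simulate_topic_data` draws documents from the multinomial topic model with
planted structure: each topic receives a disjoint block of
⌈separation·m/K⌉ anchor terms and a fraction `separation` of its mass is a
Dirichlet(1) draw over those anchors (the rest a Dirichlet(1) draw over all
terms); loadings are Dirichlet(1). separation = 1 gives fully disjoint topic
supports, 0 gives unstructured topics. Anchors make the planted factors
identifiable, so recovery experiments are meaningful. `simulate_pnmf_data`
draws **H**, **W** elementwise unit-exponential and rescales so the grand
mean rate equals `scale`. Both generators are pure functions of their
arguments including the seed.

What the generators do *not* emulate: the burstiness/overdispersion of real
text, empirical sparsity profiles and heavy-tailed word frequencies of real
corpora, or gene-length/capture biases of scRNA-seq. Passing recovery tests
therefore demonstrate correctness of the optimization and of the
model-to-model mapping, not robustness to model misspecification.

Because topic order is arbitrary (the likelihood is invariant to consistent
column permutations), estimated factors are compared to the truth after an
optimal column assignment maximizing total cosine similarity
(`match_topics`, Hungarian algorithm; checked against exhaustive search).
By multinomial chance a term may never be drawn; recovery experiments drop
empty columns and subset the true factors to the retained terms.

## Experiment sizes

The shipped checks use desk-scale problems chosen to exercise every code
path while keeping the whole suite fast: 100 random 30×40 instances for the
likelihood identity; 20 instances for the EM/multiplicative equivalence; a
100×200, K=4 data set over 200 EM iterations for monotonicity; 50 random
20×3 regressions against an independent projected-gradient oracle; 400
documents of size 1000 over 100 terms (K=3, separation 0.8, 300 CD
iterations) for recovery; and 5 replicates of 100×200 data for the
EM-vs-CD and extrapolation comparisons, every configuration branching from
an identical 10-EM-update initialization.

## Known limitations

* K is fixed by the user; no model selection.
* Maximum-likelihood / MAP point estimation only — no posterior inference,
  no held-out likelihood evaluation.
* The objective is non-convex; different seeds can reach different local
  optima. The comparisons control for this by sharing initializations.
* Subproblems are solved sequentially (the contract permits any schedule;
  a parallel map would give identical results but is not built in).
* No online/streaming variant; the full count matrix must fit in memory in
  sparse form.
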