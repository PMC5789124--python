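# Methods

## Model

A discretized trajectory X(0), X(τ), …, X(S) over states {x(0), …, x(n−1)}
is assumed Markovian: π(s+τ) = Λπ(s) with Λ column-stochastic,
Λ_ij = P[X(s+τ)=x(i) | X(s)=x(j)].  All matrices in this package are
destination-row/source-column and column-stochastic; state labels are
0-based; grid linearization is row-major with the first coordinate varying
slowest (so labels are portable across implementations).

The latent factorization replaces Λ by λ̂Γ̂, with
Γ̂_kj = P[latent(s+τ)=k | X(s)=j] (K×n) and λ̂_ik = P[X(s)=i | latent(s)=k]
(n×K), both column-stochastic.  This is a matrix-vector form of the law of
total probability through a K-state latent process; it is exact for K = n
and reduces to a memoryless model for K = 1.  The reduced operator
P̂_K = Γ̂λ̂ is K×K column-stochastic; if its eigenvalue-1 eigenvector μ̂_K
is unique, μ = λ̂μ̂_K / Σ_k (μ̂_K)_k is the invariant measure of λ̂Γ̂,
because λ̂Γ̂(λ̂μ̂_K) = λ̂(P̂_K μ̂_K) = λ̂μ̂_K.  The same identity lifts every
reduced eigenpair, which is how `spectrum` produces full-space eigenvectors
and the second-measure ratio Ψ₂ = φ₂/μ (zero where μ = 0, sign structure
separating meta-stable sets) at no extra eigensolver cost.

Latent models here are not hidden Markov models: no hidden path is
inferred; the factors relate consecutive observed states directly, which
is what makes the fit a count-matrix factorization rather than a
forward-backward problem.

## Estimators

**Empirical (full) estimator.**  Λ̂_ij = N_ij / Σ_i N_ij per source column;
zero-count source columns are undefined and filled by policy (uniform by
default, self-loop optionally) while staying flagged — an invariant-measure
request on an operator with undefined columns is refused rather than
silently answered.

**DBMR (hard Γ̂).**  With Γ̂ hard, the factorized likelihood has the closed
form  LL(γ) = Σ_k [ Σ_i S_ki log S_ki − T_k log T_k ], where S_k aggregates
the count columns assigned to latent state k and T_k = Σ_i S_ki.  The
fitter combines three exact, monotone phases on this objective:

1. *Alternating maximization* — the λ̂ update given assignments and the
   argmax reassignment of each source column are each exact; iteration
   stops at an assignment fixed point.
2. *Exact single-column moves* — the alternation scores a column against
   centroids that still contain the column's own mass.  On trajectories
   with long per-state dwell times (fine grids, small τ) this locks every
   balanced partition into a fixed point: the column's self-transition
   count dominates its score for its current cluster.  A move evaluated
   with the closed form above carries the column's mass into the target
   centroid, costs O(nnz(column)) per candidate, and is applied only when
   its exact delta is positive.
3. *Multilevel cycles* — when the random restarts disagree about the
   optimum (no majority within relative 10⁻⁶ of the best), the transition
   graph is coarsened by heavy-edge matching (symmetrized counts,
   self-loops dropped), the clustering is solved at the coarse level from
   many cheap starts, projected back, and refined with phases 1–2.  This
   is the standard escape from the near-degenerate local optima of
   dwell-dominated data; on the Lorenz benchmark it is what separates the
   attractor wings where plain restarts return arbitrary partitions of
   equal-looking quality.

Initialization: one deterministic start (column j → j mod K) plus
`restarts` seeded uniform-random ones; ties in the argmax go to the lowest
latent index; a cluster emptied by reassignment is repaired by donating the
worst-fitting column of a multi-member cluster, and the iteration returns
the previous best configuration if a repair would lower the objective —
the recorded trace is therefore non-decreasing for every fit.  Scoring
treats a zero model probability of an observed transition as −∞ (no
ε-flooring inside the likelihood); a column whose every candidate scores
−∞ falls back to the latent state with the largest count-weighted support
overlap.

**PLSA (soft Γ̂).**  Standard EM on the same likelihood: responsibilities
r[k|i,j] ∝ λ̂_ik Γ̂_kj, M-step re-estimates both factors from
responsibility-weighted counts with column renormalization.  Initialization
is seeded random column-stochastic; monotonicity is the usual EM guarantee.

## Model selection and uncertainty

Free parameters follow column-stochastic counting: n(n−1) for the full
operator, K(n−1) + n(K−1) for a latent model (hard models are counted with
the same formula — conservative for the assignment structure).  The latent
model is smaller exactly when K < n²/(2n−1); `max_latent_dim` returns the
largest admissible integer (100 at n = 200).  AIC = −2LL + 2p and
BIC = −2LL + p·ln M use M = number of observed transitions, not the frame
count.  Cross-validation splits the trajectory contiguously in time
(default 50/50) to respect temporal dependence; validation probabilities
are floored at reg_eps/n (default reg_eps = 10⁻⁶) and column-renormalized,
applied in validation scoring only, never in training.  The bootstrap
resamples the M observed transition pairs with replacement — the
independent units of the likelihood — refits, recomputes μ, and reports
per-state quantile envelopes (default 2.5%/97.5%); replicates with a
reducible reduced operator are dropped and counted.

## Numerical choices

* Eigenproblems: dense for n ≤ 300 (and always for P̂_K, since K is small
  by construction), sparse Lanczos above; the power-iteration alternative
  stops on successive-iterate ℓ₁ change < tol.
* Reducibility: before solving, the closed communicating classes of the
  support graph are computed (strongly connected components without
  outgoing edges); more than one closed class aborts with the class
  memberships rather than silently returning one basin.  A single
  absorbing class with transient feeders is *not* an error — that is the
  regime in which the empirical estimator collapses onto the trap while
  the latent model does not.
* Eigenvector cleanup: entries below −10⁻⁸ (relative) are an error; small
  negatives are clipped and the vector renormalized.
* Convergence defaults: tol = 10⁻⁸ relative likelihood change,
  max_iter = 500 for both fitters.
* Out-of-grid points are clamped into boundary bins with a logged warning:
  adaptive-step trajectories can graze a bounding box estimated from the
  data itself.  Data-driven grids pad the bounding box by 1% per side.
* Spectrum sign convention: each lifted vector is ℓ₁-normalized with its
  largest-modulus entry rotated to the positive real axis; a complex
  second eigenvalue is returned as-is with a warning.

## Synthetic data

The generators define the study conditions for every test:

* **Lorenz-63** — σ = 10, ρ = 28, β = 8/3, classical fixed-step RK4 at
  dt = 10⁻³ (adaptive integrators trade determinism for little accuracy at
  this step; 4th-order convergence is verified by step-halving), initial
  state (1,1,1), 10⁴ burn-in steps to land on the attractor, 2×10⁵ retained
  samples.  The benchmark grid is 20×20×20 over the padded data bounding
  box (≈750 occupied boxes) — coarse enough for a desk-scale run while
  keeping the two attractor wings resolvable.
* **Chain samplers** realize the master equation generatively (two-stage
  draws through Γ̂ then λ̂ for latent models); fixed seeds give
  bit-identical trajectories.
* **Planted models** partition n states into K near-equal groups; λ̂
  column k holds `separation` mass uniformly on group k and leaks the rest
  uniformly elsewhere; Γ̂ is hard, sending group g to latent state perm[g]
  for a seeded permutation.  Defaults (n = 60, K = 3, separation = 0.9,
  2×10⁵ transitions) give exact partition recovery with λ̂ entry errors of
  a few 10⁻³.
* **Trap chains** append a one-way absorbing tail occupying 1% of frames
  to a planted recurrent part.  The trajectory length (5×10³ frames) is
  chosen so that BIC's complexity penalty exceeds the likelihood gain of
  isolating the trap column into its own latent state; much longer
  trajectories at the same 1% trap share would legitimately select an
  absorbing latent state instead.

What the generators do **not** emulate: observation noise, non-Markovian
memory in the observed process, non-stationarity, and the featurization
and projection steps that precede discretization in molecular-dynamics
workflows.  Passing tests show the estimators are correct and
well-behaved under the stated generative conditions, not that any
particular real dataset is Markovian at the chosen lag.

## Problem sizes

The shipped tests and the acceptance script run the Lorenz benchmark at
2×10⁵ samples on a 20³ grid, planted instances at n ≤ 60 with 2×10⁵
transitions, and bootstrap/cross-validation loops at n ≤ 20 with tens of
replicates — sizes chosen so a full run completes in a few minutes on one
CPU while every qualitative conclusion (wing decomposition, exact
recovery, BIC consistency, trap robustness) is already stable.

## Known limitations

* The DBMR objective is non-convex; the multilevel phase makes the wing
  decomposition reproducible across seeds, but global optimality is not
  certified.
* Cross-validation uses a single contiguous split (no block bootstrap or
  multiple folds); reversible (detailed-balance-constrained) estimation
  and adaptive discretizations are out of scope.
* The bootstrap treats transition pairs as independent, which understates
  uncertainty for slowly mixing chains.
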