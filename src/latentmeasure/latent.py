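"""Latent Markov models: the factorized master equation and its fitters.

The full master equation pi(s+tau) = Lambda pi(s) is replaced by the exact
latent factorization

    pi(s+tau) = lam Gamma pi(s)

where Gamma (K x n, column-stochastic) maps observed states to next-step
latent states and lam (n x K, column-stochastic) maps latent states back to
observed states.  The reduced transfer operator P_K = Gamma lam is K x K and
column-stochastic; its dominant eigenvector mu_K, lifted through lam,

    mu = lam mu_K / sum_k (mu_K)_k,

is the invariant measure of the full n-state chain induced by lam Gamma.

Two fitters maximize the factorized log-likelihood
L = sum_ij N_ij log((lam Gamma)_ij):

* ``fit_dbmr`` — hard clustering of source columns (Gamma entries exactly
  0/1), by alternating exact maximization over lam and over assignments;
* ``fit_plsa`` — expectation-maximization yielding soft Gamma.

K interpolates between a memoryless Bernoulli model (K=1, mu = empirical
p.d.f.) and the common full Markov model (K=n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import NumericalError, ReducibleOperatorError, ValidationError
from .ulam import InvariantMeasure, TransitionCounts, _closed_classes

_STOCHASTIC_ATOL = 1e-12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentModel:
    """The pair (Gamma, lam) of a K-dimensional latent factorization.

    gamma[k, j] = P[latent next state = k | observed state = j]  (K x n)
    lam[i, k]   = P[observed state = i | latent state = k]       (n x K)

    ``hard`` marks models whose Gamma columns are 0/1 unit vectors (DBMR).
    """

    gamma: np.ndarray
    lam: np.ndarray
    hard: bool = False

    def __post_init__(self):
        gamma = np.asarray(self.gamma, dtype=float)
        lam = np.asarray(self.lam, dtype=float)
        if gamma.ndim != 2 or lam.ndim != 2:
            raise ValidationError("gamma and lam must be 2-D")
        K, n = gamma.shape
        if lam.shape != (n, K):
            raise ValidationError(
                f"shape mismatch: gamma is {gamma.shape}, lam is {lam.shape}"
            )
        if not 1 <= K <= n:
            raise ValidationError(f"latent dimension K={K} must satisfy 1 <= K <= n={n}")
        if gamma.min() < -_STOCHASTIC_ATOL or lam.min() < -_STOCHASTIC_ATOL:
            raise ValidationError("factor entries must be nonnegative")
        if np.any(np.abs(gamma.sum(axis=0) - 1.0) > 1e-9):
            raise ValidationError("every column of gamma must sum to 1")
        if np.any(np.abs(lam.sum(axis=0) - 1.0) > 1e-9):
            raise ValidationError("every column of lam must sum to 1")
        if self.hard:
            if np.any(np.count_nonzero(gamma, axis=0) != 1) or not np.allclose(
                gamma.max(axis=0), 1.0, atol=_STOCHASTIC_ATOL
            ):
                raise ValidationError(
                    "hard models require each gamma column to be a 0/1 unit vector"
                )
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "lam", lam)

    @property
    def K(self) -> int:
        return self.gamma.shape[0]

    @property
    def n(self) -> int:
        return self.gamma.shape[1]

    @property
    def assignments(self) -> np.ndarray:
        """Source-column -> latent-state map (argmax of each gamma column)."""
        return np.argmax(self.gamma, axis=0)


@dataclass(frozen=True)
class ReducedOperator:
    """The K x K column-stochastic reduced transfer operator P_K = Gamma lam."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("reduced operator must be square")
        if m.min() < -_STOCHASTIC_ATOL:
            raise ValidationError("reduced operator entries must be nonnegative")
        colsums = m.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValidationError("reduced operator must be column-stochastic")
        object.__setattr__(self, "matrix", np.clip(m, 0.0, None) / colsums)

    @property
    def K(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class FitDiagnostics:
    """Bookkeeping of a likelihood maximization run.

    ``trace`` records the objective of the returned run after every
    accepted update, so it is non-decreasing.  ``refined`` marks fits whose
    best run came from a multilevel coarsening cycle rather than a plain
    restart.
    """

    trace: np.ndarray
    iterations: int
    restarts: int
    best_restart: int
    converged: bool
    seed: int
    repairs: int = 0
    refined: bool = False

    @property
    def log_likelihood(self) -> float:
        return float(self.trace[-1])


@dataclass(frozen=True)
class SpectralComponents:
    """Eigen-structure of the reduced operator lifted to the full space.

    Eigenvalues are sorted by modulus (descending).  Each lifted vector
    ``vectors[:, m] = lam v_m`` is an eigenvector of lam Gamma for the same
    eigenvalue, scaled to unit l1 norm with its largest-modulus entry made
    positive real.  ``psi2`` is the second invariant measure divided
    entrywise by the first (zero where mu is zero); its sign structure
    separates meta-stable sets.
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray
    psi2: np.ndarray | None


# ---------------------------------------------------------------------------
# DBMR fitter (hard Gamma)
# ---------------------------------------------------------------------------

def _log_lam(lam: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        out = np.where(lam > 0, np.log(np.clip(lam, np.finfo(float).tiny, None)), 0.0)
    return out


def _column_scores(N: sp.csc_matrix, lam: np.ndarray) -> np.ndarray:
    """scores[k, j] = sum_i N_ij log lam[i, k]; -inf where an observed
    transition has probability 0 under latent state k."""
    scores = (N.T @ _log_lam(lam)).T  # (K, n)
    npos = (N != 0).astype(np.int8)
    bad = (npos.T @ (lam <= 0)).T > 0  # (K, n)
    scores = np.asarray(scores, dtype=float)
    scores[np.asarray(bad)] = -np.inf
    return scores


def _support_overlap(N: sp.csc_matrix, lam: np.ndarray) -> np.ndarray:
    """overlap[k, j] = sum_i N_ij [lam_ik > 0] — fallback assignment score."""
    return np.asarray((N.T @ (lam > 0).astype(float)).T)


def _lam_from_assignments(
    N: sp.csc_matrix, assign: np.ndarray, K: int
) -> np.ndarray:
    n = N.shape[0]
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), assign)), shape=(n, K)
    )
    agg = np.asarray((N @ Z).todense(), dtype=float)  # (n, K)
    tot = agg.sum(axis=0)
    lam = np.empty_like(agg)
    nonzero = tot > 0
    lam[:, nonzero] = agg[:, nonzero] / tot[nonzero]
    lam[:, ~nonzero] = 1.0 / n  # cluster of never-source columns: no data
    return lam


def _assign_ll(scores: np.ndarray, assign: np.ndarray) -> float:
    return float(scores[assign, np.arange(assign.size)].sum())


def _repair_empty_clusters(
    assign: np.ndarray, K: int, scores: np.ndarray
) -> int:
    """Move the worst-fitting column (from a multi-member cluster) into each
    empty cluster; returns the number of repairs performed."""
    repairs = 0
    counts = np.bincount(assign, minlength=K)
    for k in np.flatnonzero(counts == 0):
        contrib = scores[assign, np.arange(assign.size)]
        movable = np.bincount(assign, minlength=K)[assign] > 1
        if not movable.any():
            break
        candidates = np.where(movable, contrib, np.inf)
        j = int(np.argmin(candidates))
        assign[j] = k
        repairs += 1
    return repairs


def _dbmr_single(
    N: sp.csc_matrix,
    K: int,
    assign0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, list[float], bool, int]:
    """One DBMR run; returns (assign, lam, trace, converged, repairs)."""
    assign = assign0.copy()
    n = N.shape[0]
    trace: list[float] = []
    total_repairs = 0
    # repair an initialization that already misses clusters
    if np.bincount(assign, minlength=K).min() == 0:
        lam0 = _lam_from_assignments(N, assign, K)
        total_repairs += _repair_empty_clusters(assign, K, _column_scores(N, lam0))
    converged = False
    best = None  # (ll, assign, lam)
    for _ in range(max_iter):
        lam = _lam_from_assignments(N, assign, K)
        scores = _column_scores(N, lam)
        ll = _assign_ll(scores, assign)
        if trace and ll < trace[-1] - tol * max(1.0, abs(trace[-1])):
            # can only happen after an empty-cluster repair; keep the best
            converged = True
            break
        trace.append(ll)
        if best is None or ll >= best[0]:
            best = (ll, assign.copy(), lam)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * max(1.0, abs(trace[-2])):
            converged = True
            break
        new_assign = np.argmax(scores, axis=0)  # ties: lowest latent index
        dead = ~np.isfinite(scores.max(axis=0))
        if dead.any():
            overlap = _support_overlap(N, lam)
            new_assign[dead] = np.argmax(overlap[:, dead], axis=0)
        if np.array_equal(new_assign, assign):
            converged = True
            break
        assign = new_assign
        if np.bincount(assign, minlength=K).min() == 0:
            total_repairs += _repair_empty_clusters(assign, K, scores)
    ll, assign, lam = best
    return assign, lam, trace, converged, total_repairs


def _hard_gamma(assign: np.ndarray, K: int) -> np.ndarray:
    gamma = np.zeros((K, assign.size))
    gamma[assign, np.arange(assign.size)] = 1.0
    return gamma


# -- exact single-column moves ----------------------------------------------
#
# With hard Gamma the likelihood has the closed form
#     LL = sum_k [ sum_i S_ki log S_ki  -  T_k log T_k ],
# where S_k is the aggregated count column of cluster k and T_k its total.
# Moving one source column between clusters therefore has an O(nnz(column))
# exact delta.  These moves carry the column's own self-transition mass along
# with it — unlike the plain assignment step, which holds the centroids
# fixed and is easily locked in place by self-loop-dominated columns (long
# dwell times in a box).

def _xlogx(a: np.ndarray) -> np.ndarray:
    return np.where(a > 0, a * np.log(np.where(a > 0, a, 1.0)), 0.0)


def _tlogt(x: float) -> float:
    return x * np.log(x) if x > 0 else 0.0


def _aggregate(N: sp.csc_matrix, assign: np.ndarray, K: int) -> np.ndarray:
    n = N.shape[0]
    Z = sp.csr_matrix((np.ones(n), (np.arange(n), assign)), shape=(n, K))
    return np.asarray((N @ Z).todense(), dtype=float)


def _closed_ll(S: np.ndarray, T: np.ndarray) -> float:
    return float(_xlogx(S).sum() - _xlogx(T).sum())


def _greedy_sweeps(
    N: sp.csc_matrix,
    assign: np.ndarray,
    K: int,
    max_sweeps: int = 100,
) -> tuple[np.ndarray, float, list[float]]:
    """Exact coordinate ascent over single-column cluster moves.

    Monotone by construction: a move is applied only if its exact
    likelihood delta is positive.  Moves that would empty a cluster are
    skipped (K stays fixed).  Returns (assign, ll, per-sweep ll trace).
    """
    assign = assign.copy()
    n = N.shape[0]
    S = _aggregate(N, assign, K)
    T = S.sum(axis=0)
    sizes = np.bincount(assign, minlength=K)
    ll = _closed_ll(S, T)
    trace: list[float] = []
    indptr, indices, data = N.indptr, N.indices, N.data
    for _ in range(max_sweeps):
        improved = False
        for c in range(n):
            a = assign[c]
            if sizes[a] <= 1:
                continue
            lo, hi = indptr[c], indptr[c + 1]
            idx = indices[lo:hi]
            v = data[lo:hi]
            m = v.sum()
            if m == 0:
                continue
            Sa = S[idx, a]
            d_rm = float((_xlogx(Sa - v) - _xlogx(Sa)).sum()) - (
                _tlogt(T[a] - m) - _tlogt(T[a])
            )
            best_d, best_b = 1e-9, -1
            for b in range(K):
                if b == a:
                    continue
                Sb = S[idx, b]
                d = d_rm + float((_xlogx(Sb + v) - _xlogx(Sb)).sum()) - (
                    _tlogt(T[b] + m) - _tlogt(T[b])
                )
                if d > best_d:
                    best_d, best_b = d, b
            if best_b >= 0:
                S[idx, a] -= v
                S[idx, best_b] += v
                T[a] -= m
                T[best_b] += m
                sizes[a] -= 1
                sizes[best_b] += 1
                assign[c] = best_b
                ll += best_d
                improved = True
        if not improved:
            break
        trace.append(ll)
    return assign, ll, trace


# -- multilevel initialization ----------------------------------------------
#
# Heavy-edge matching coarsens the transition graph (symmetrized, self-loops
# dropped) until it is small, the clustering is solved exhaustively-ish at
# the coarse level, and the result is projected back and refined.  This is
# the standard escape from the many near-degenerate local optima that plain
# restarts fall into on trajectories with long per-state dwell times.

def _coarsen_once(C: sp.csc_matrix, rng) -> tuple[sp.csc_matrix, np.ndarray]:
    m = C.shape[0]
    W = (C + C.T).tolil()
    W.setdiag(0)
    W = W.tocsr()
    order = rng.permutation(m)
    match = np.full(m, -1, dtype=np.int64)
    for u in order:
        if match[u] >= 0:
            continue
        lo, hi = W.indptr[u], W.indptr[u + 1]
        best, bw = -1, 0.0
        for v, w in zip(W.indices[lo:hi], W.data[lo:hi]):
            if match[v] < 0 and v != u and w > bw:
                best, bw = int(v), w
        if best >= 0:
            match[u] = best
            match[best] = u
        else:
            match[u] = u
    cid = np.full(m, -1, dtype=np.int64)
    nxt = 0
    for u in range(m):
        if cid[u] < 0:
            cid[u] = nxt
            if match[u] != u:
                cid[match[u]] = nxt
            nxt += 1
    P = sp.csr_matrix((np.ones(m), (np.arange(m), cid)), shape=(m, nxt))
    return sp.csc_matrix(P.T @ C @ P), cid


def _multilevel_assign(
    N: sp.csc_matrix, K: int, rng, tol: float, max_iter: int
) -> np.ndarray:
    coarse_target = max(4 * K, 24)
    levels: list[np.ndarray] = []
    C = N
    while C.shape[0] > coarse_target:
        C2, cid = _coarsen_once(C, rng)
        if C2.shape[0] >= C.shape[0]:
            break
        levels.append(cid)
        C = C2
    m = C.shape[0]
    best = None
    for r in range(30):
        a0 = (np.arange(m) % K) if r == 0 else rng.integers(0, K, size=m)
        a, _, tr, _, _ = _dbmr_single(C.astype(float), K, a0, tol, max_iter)
        a, ll, _ = _greedy_sweeps(C.astype(float), a, K)
        if best is None or ll > best[0]:
            best = (ll, a)
    assign = best[1]
    for cid in reversed(levels):
        assign = assign[cid]
    return assign


def _local_fit(
    N: sp.csc_matrix,
    K: int,
    a0: np.ndarray,
    tol: float,
    max_iter: int,
    polish: bool = True,
) -> tuple[np.ndarray, list[float], bool, int]:
    """Alternating maximization followed by exact single-column sweeps.

    The combined trace (alternation iterations, then one entry per
    improving sweep) is non-decreasing."""
    assign, _, trace, conv, repairs = _dbmr_single(N, K, a0, tol, max_iter)
    if polish and K > 1:
        assign, ll, sweep_trace = _greedy_sweeps(N, assign, K)
        trace = trace + sweep_trace
    return assign, trace, conv, repairs


def fit_dbmr(
    counts: TransitionCounts,
    K: int,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    init: np.ndarray | None = None,
    refine: str = "auto",
) -> tuple[LatentModel, FitDiagnostics]:
    """Direct Bayesian model reduction: hard clustering of source columns.

    Each run alternates (a) the exact lam update given assignments —
    lam[:, k] is the normalized aggregate of the count columns assigned to
    latent state k — and (b) the exact reassignment of each source column j
    to argmax_k sum_i N_ij log lam[i, k], to a fixed point, and then
    polishes with exact single-column moves (which, unlike step (b), carry
    a column's self-transition mass along and so escape dwell-time
    lock-in).

    Runs one deterministic initialization (column j -> j mod K) plus
    ``restarts`` seeded uniform-random ones (or a single caller-provided
    ``init``).  With ``refine="auto"``, when the restarts disagree about
    the optimum (no majority within relative 1e-6 of the best) additional
    multilevel coarsen-solve-refine cycles are run; ``refine="sweeps"``
    disables the multilevel phase (cheaper, for resampling loops).
    """
    n = counts.n
    if not 1 <= K <= n:
        raise ValidationError(f"K={K} must satisfy 1 <= K <= n={n}")
    if counts.total == 0:
        raise ValidationError("counts must contain at least one observed transition")
    if refine not in ("auto", "sweeps", "none"):
        raise ValidationError(f"unknown refine mode {refine!r}")
    N = counts.matrix.tocsc().astype(float)
    polish = refine != "none"

    rng = np.random.default_rng(seed)
    if init is not None:
        init = np.asarray(init, dtype=np.int64)
        if init.shape != (n,) or init.min() < 0 or init.max() >= K:
            raise ValidationError("init must be a length-n assignment into [0, K)")
        starts = [init]
    else:
        starts = [np.arange(n, dtype=np.int64) % K]
        starts += [rng.integers(0, K, size=n) for _ in range(restarts)]

    runs = []
    for r, a0 in enumerate(starts):
        assign, trace, conv, repairs = _local_fit(N, K, a0, tol, max_iter, polish)
        runs.append((trace[-1], r, assign, trace, conv, repairs))
    best = max(runs, key=lambda t: t[0])

    refined = False
    if refine == "auto" and init is None and 1 < K <= n // 2:
        near = sum(
            1 for t in runs if t[0] >= best[0] - 1e-6 * max(1.0, abs(best[0]))
        )
        if near <= len(runs) // 2:
            for cycle in range(5):
                a0 = _multilevel_assign(N, K, rng, tol, max_iter)
                assign, trace, conv, repairs = _local_fit(N, K, a0, tol, max_iter)
                runs.append((trace[-1], len(runs), assign, trace, conv, repairs))
                if trace[-1] > best[0]:
                    best = runs[-1]
                    refined = True

    ll, r, assign, trace, conv, repairs = best
    lam = _lam_from_assignments(N, assign, K)
    model = LatentModel(_hard_gamma(assign, K), lam, hard=True)
    diag = FitDiagnostics(
        trace=np.asarray(trace),
        iterations=len(trace),
        restarts=len(runs),
        best_restart=r,
        converged=conv,
        seed=seed,
        repairs=repairs,
        refined=refined,
    )
    return model, diag


# ---------------------------------------------------------------------------
# PLSA fitter (soft Gamma, EM)
# ---------------------------------------------------------------------------

def _plsa_single(
    i_arr: np.ndarray,
    j_arr: np.ndarray,
    v: np.ndarray,
    n: int,
    K: int,
    lam: np.ndarray,
    gamma: np.ndarray,
    col_tot: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        num = lam[i_arr, :] * gamma[:, j_arr].T  # (nnz, K)
        p = num.sum(axis=1)
        if np.any(p <= 0):
            ll = -np.inf
        else:
            ll = float(v @ np.log(p))
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * max(1.0, abs(trace[-2])):
            converged = True
            break
        resp = (v / p)[:, None] * num  # responsibility-weighted counts
        lam_acc = np.zeros((n, K))
        np.add.at(lam_acc, i_arr, resp)
        lam_tot = lam_acc.sum(axis=0)
        lam = np.where(lam_tot > 0, lam_acc / np.where(lam_tot > 0, lam_tot, 1.0), 1.0 / n)
        g_acc = np.zeros((n, K))
        np.add.at(g_acc, j_arr, resp)
        gamma = np.where(
            col_tot[None, :] > 0,
            g_acc.T / np.where(col_tot > 0, col_tot, 1.0)[None, :],
            1.0 / K,
        )
    return lam, gamma, trace, converged


def fit_plsa(
    counts: TransitionCounts,
    K: int,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[LatentModel, FitDiagnostics]:
    """EM on the factorized likelihood (probabilistic latent semantic
    analysis applied to the transition count matrix), yielding a soft Gamma.

    E-step: responsibilities r[k|i,j] proportional to lam[i,k] gamma[k,j];
    M-step: re-estimate both factors from responsibility-weighted counts
    with column renormalization.  The likelihood trace is monotone
    non-decreasing (standard EM guarantee).
    """
    n = counts.n
    if not 1 <= K <= n:
        raise ValidationError(f"K={K} must satisfy 1 <= K <= n={n}")
    if counts.total == 0:
        raise ValidationError("counts must contain at least one observed transition")
    coo = counts.matrix.tocoo()
    i_arr, j_arr, v = coo.row, coo.col, coo.data.astype(float)
    col_tot = np.asarray(counts.matrix.sum(axis=0)).ravel().astype(float)

    rng = np.random.default_rng(seed)
    best = None
    n_runs = max(1, restarts)
    for r in range(n_runs):
        lam0 = rng.uniform(0.1, 1.0, size=(n, K))
        lam0 /= lam0.sum(axis=0)
        g0 = rng.uniform(0.1, 1.0, size=(K, n))
        g0 /= g0.sum(axis=0)
        lam, gamma, trace, conv = _plsa_single(
            i_arr, j_arr, v, n, K, lam0, g0, col_tot, tol, max_iter
        )
        ll = trace[-1]
        if best is None or ll > best[0]:
            best = (ll, r, lam, gamma, trace, conv)
    ll, r, lam, gamma, trace, conv = best
    # never-source columns have arbitrary gamma; make them exactly uniform
    gamma = np.clip(gamma, 0.0, None)
    gamma /= gamma.sum(axis=0)
    lam = np.clip(lam, 0.0, None)
    lam /= lam.sum(axis=0)
    model = LatentModel(gamma, lam, hard=False)
    diag = FitDiagnostics(
        trace=np.asarray(trace),
        iterations=len(trace),
        restarts=n_runs,
        best_restart=r,
        converged=conv,
        seed=seed,
    )
    return model, diag


# ---------------------------------------------------------------------------
# Reduced operator, invariant measure, propagation, spectrum
# ---------------------------------------------------------------------------

def reduced_operator(model: LatentModel) -> ReducedOperator:
    """P_K = Gamma lam, with accumulated rounding renormalized away."""
    return ReducedOperator(model.gamma @ model.lam)


def latent_invariant_measure(
    model: LatentModel, tol: float = 1e-9
) -> tuple[InvariantMeasure, np.ndarray]:
    """Invariant measure via the reduced operator (Perron-Frobenius lift).

    Solves the K x K dense eigenproblem for P_K, takes the eigenvector for
    the eigenvalue of maximal real part within ``tol`` of 1, and lifts it:
    mu = lam mu_K / sum_k (mu_K)_k.

    Returns (mu, mu_K).  Raises ReducibleOperatorError when the dominant
    eigenvalue is degenerate (disconnected latent blocks).
    """
    P = reduced_operator(model).matrix
    K = P.shape[0]
    if K == 1:
        mu_K = np.array([1.0])
    else:
        vals, vecs = np.linalg.eig(P)
        close = np.abs(vals - 1.0) < max(tol, 1e-12)
        if close.sum() > 1:
            blocks = [b.tolist() for b in _closed_classes(sp.csr_matrix(P))]
            raise ReducibleOperatorError(
                f"reduced operator is reducible: eigenvalue 1 has multiplicity "
                f"{int(close.sum())}; closed latent blocks {blocks}",
                blocks=blocks,
            )
        if close.sum() == 0:
            raise NumericalError(
                f"no eigenvalue of the reduced operator within {tol} of 1 "
                f"(closest: {vals[np.argmin(np.abs(vals - 1.0))]!r})"
            )
        k = int(np.argmax(np.where(close, vals.real, -np.inf)))
        mu_K = np.real(vecs[:, k])
        if mu_K.sum() < 0:
            mu_K = -mu_K
        mu_K = np.clip(mu_K, 0.0, None)
    mu_K = mu_K / mu_K.sum()
    mu = model.lam @ mu_K
    return InvariantMeasure(mu / mu.sum()), mu_K


def propagate(model: LatentModel, pi: np.ndarray) -> np.ndarray:
    """One master-equation step: lam (Gamma pi), as two rectangular products
    (the n x n product lam Gamma is never materialized)."""
    pi = np.asarray(pi, dtype=float).ravel()
    if pi.shape != (model.n,):
        raise ValidationError(f"pi must have length n={model.n}")
    if pi.min() < -1e-12 or abs(pi.sum() - 1.0) > 1e-9:
        raise ValidationError("pi must be a probability vector (nonnegative, sum 1)")
    out = model.lam @ (model.gamma @ pi)
    return out / out.sum()


def spectrum(model: LatentModel, n_components: int = 2) -> SpectralComponents:
    """Eigen-decomposition of P_K lifted to the full n-dimensional space.

    Uses the identity P_K v = z v  =>  (lam Gamma)(lam v) = z (lam v), so
    each reduced eigenvector lifts to a full-space eigenvector at zero extra
    eigensolver cost.  The second lifted vector, divided entrywise by mu
    where mu > 0, is the second invariant measure ratio psi2 whose sign
    structure separates meta-stable sets.
    """
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    if n_components > model.K:
        raise ValidationError(
            f"n_components={n_components} exceeds the latent dimension K={model.K}"
        )
    P = reduced_operator(model).matrix
    vals, vecs = np.linalg.eig(P)
    # sort by modulus desc; tie-break on real part then imaginary for determinism
    order = np.lexsort((-vals.imag, -vals.real, -np.abs(vals)))
    vals, vecs = vals[order], vecs[:, order]
    if abs(vals[0] - 1.0) > 1e-9:
        raise NumericalError(
            f"leading eigenvalue {vals[0]!r} deviates from 1 beyond tolerance"
        )
    if n_components >= 2 and abs(vals[1].imag) > 1e-12:
        warnings.warn(
            "second eigenvalue is complex; returning it as-is", stacklevel=2
        )
    lifted = np.empty((model.n, n_components), dtype=complex)
    for m in range(n_components):
        v = model.lam @ vecs[:, m]
        norm = np.abs(v).sum()
        if norm > 0:
            v = v / norm
        peak = v[np.argmax(np.abs(v))]
        if np.abs(peak) > 0:
            v = v * (np.conj(peak) / np.abs(peak))  # largest entry positive real
        lifted[:, m] = v
    if np.abs(lifted.imag).max(initial=0.0) < 1e-12:
        lifted = lifted.real.astype(float)
    mu = np.real(lifted[:, 0])
    mu = np.clip(mu, 0.0, None)
    mu /= mu.sum()
    psi2 = None
    if n_components >= 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            psi2 = np.where(mu > 0, lifted[:, 1] / np.where(mu > 0, mu, 1.0), 0.0)
    return SpectralComponents(eigenvalues=vals[:n_components], vectors=lifted, psi2=psi2)
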