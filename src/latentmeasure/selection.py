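"""Model scoring and selection of the latent dimension K.

Scoring uses the observational log-likelihood L = sum_ij N_ij log p_ij with
p the model's one-step transition probability.  Free-parameter counting
follows column-stochastic columns: n(n-1) for the full operator,
K(n-1) + n(K-1) for a latent factorization, which makes the latent model
smaller exactly when K < n^2/(2n-1) — the overfitting bound on K.

Selection is offered through AIC/BIC (sample size = number of observed
transitions), temporally contiguous cross-validation, and nonparametric
bootstrap confidence envelopes for the invariant measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError, NumericalError, ReducibleOperatorError
from .latent import LatentModel, fit_dbmr, fit_plsa, latent_invariant_measure
from .ulam import (
    DiscreteTrajectory,
    TransferOperator,
    TransitionCounts,
    count_transitions,
    empirical_estimator,
)

_FITTERS = {"dbmr": fit_dbmr, "plsa": fit_plsa}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelScore:
    label: str
    K: int
    log_likelihood: float
    n_parameters: int
    aic: float
    bic: float
    sample_size: int
    degenerate: bool = False  # -inf likelihood encountered


@dataclass(frozen=True)
class CVResult:
    label: str
    K: int
    train_log_likelihood: float
    validation_log_likelihoods: tuple
    mean_validation: float


@dataclass(frozen=True)
class BootstrapResult:
    """Per-state quantile envelopes for the invariant measure."""

    lower: np.ndarray
    upper: np.ndarray
    point: np.ndarray
    n_replicates: int
    n_dropped: int
    quantiles: tuple


# ---------------------------------------------------------------------------
# Likelihood and parameter counting
# ---------------------------------------------------------------------------

def log_likelihood(counts: TransitionCounts, model) -> float:
    """L = sum over observed entries of N_ij log p_ij.

    ``model`` is a TransferOperator or a LatentModel; for the latter the
    probability (lam Gamma)_ij is assembled per nonzero count entry from the
    factors, never materializing the n x n product.  Returns -inf if any
    observed transition has probability zero (no flooring in scoring mode).
    """
    i_arr, j_arr, v = counts.pairs()
    if isinstance(model, LatentModel):
        if model.n != counts.n:
            raise ValidationError(
                f"model has n={model.n}, counts have n={counts.n}"
            )
        p = np.einsum("ek,ek->e", model.lam[i_arr, :], model.gamma[:, j_arr].T)
    elif isinstance(model, TransferOperator):
        if model.n != counts.n:
            raise ValidationError(
                f"operator has n={model.n}, counts have n={counts.n}"
            )
        p = np.asarray(model.matrix[i_arr, j_arr]).ravel()
    else:
        raise ValidationError(f"cannot score object of type {type(model).__name__}")
    if v.size == 0:
        return 0.0
    if np.any(p <= 0):
        return -np.inf
    return float(v @ np.log(p))


def free_parameters(kind: str, n: int, K: int | None = None) -> int:
    """Free parameters of a column-stochastic model.

    full:   n columns of n-1 free entries each -> n(n-1)
    latent: K(n-1) for lam plus n(K-1) for Gamma
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if kind == "full":
        return n * (n - 1)
    if kind == "latent":
        if K is None or not 1 <= K <= n:
            raise ValidationError(f"latent models need 1 <= K <= n (got K={K})")
        return K * (n - 1) + n * (K - 1)
    raise ValidationError(f"unknown model kind {kind!r}")


def max_latent_dim(n: int) -> int:
    """Largest K with strictly fewer free parameters than the full model,
    i.e. the largest integer K satisfying K < n^2 / (2n - 1)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    return (n * n - 1) // (2 * n - 1)


# ---------------------------------------------------------------------------
# Information-criterion scoring
# ---------------------------------------------------------------------------

def score_models(
    counts: TransitionCounts,
    models: list[tuple[str, object]],
    criterion: str = "bic",
) -> list[ModelScore]:
    """Score a list of (label, TransferOperator-or-LatentModel) candidates.

    AIC = -2 L + 2 p, BIC = -2 L + p ln(M) with M the number of observed
    transitions.  A model with -inf likelihood is kept with +inf criteria
    and flagged ``degenerate`` rather than raising.  Returned sorted
    ascending by the requested criterion.
    """
    if criterion not in ("aic", "bic"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    M = counts.total
    if M <= 0:
        raise ValidationError("counts must contain observed transitions")
    out = []
    for label, model in models:
        if isinstance(model, LatentModel):
            p = free_parameters("latent", model.n, model.K)
            K = model.K
        else:
            p = free_parameters("full", counts.n)
            K = counts.n
        ll = log_likelihood(counts, model)
        if np.isfinite(ll):
            aic = -2.0 * ll + 2.0 * p
            bic = -2.0 * ll + p * np.log(M)
            degenerate = False
        else:
            aic = bic = np.inf
            degenerate = True
        out.append(
            ModelScore(
                label=label,
                K=K,
                log_likelihood=ll,
                n_parameters=p,
                aic=aic,
                bic=bic,
                sample_size=M,
                degenerate=degenerate,
            )
        )
    key = (lambda s: s.bic) if criterion == "bic" else (lambda s: s.aic)
    return sorted(out, key=key)


def fit_k_range(
    counts: TransitionCounts,
    Ks,
    fitter: str = "dbmr",
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> list[tuple[str, LatentModel]]:
    """Fit one latent model per K; convenience for selection workflows."""
    if fitter not in _FITTERS:
        raise ValidationError(f"unknown fitter {fitter!r}")
    fit = _FITTERS[fitter]
    Ks = list(Ks)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(Ks))]
    out = []
    for K, s in zip(Ks, seeds):
        model, _ = fit(counts, K, restarts=restarts, seed=s, tol=tol, max_iter=max_iter)
        out.append((f"{fitter}-K{K}", model))
    return out


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _floored_probabilities(model, n: int, reg_eps: float) -> np.ndarray:
    """Dense transition matrix with probabilities floored at reg_eps/n and
    columns renormalized; used for validation scoring only."""
    if isinstance(model, LatentModel):
        P = model.lam @ model.gamma
    else:
        P = model.toarray()
    if reg_eps > 0:
        P = np.maximum(P, reg_eps / n)
        P = P / P.sum(axis=0)
    return P


def _score_dense(counts: TransitionCounts, P: np.ndarray) -> float:
    i_arr, j_arr, v = counts.pairs()
    p = P[i_arr, j_arr]
    if np.any(p <= 0):
        return -np.inf
    return float(v @ np.log(p))


def cross_validate(
    traj: DiscreteTrajectory,
    Ks,
    fitter: str = "dbmr",
    split_fraction: float = 0.5,
    reg_eps: float = 1e-6,
    seed: int = 0,
    restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> list[CVResult]:
    """Temporally contiguous train/validation split for K selection.

    The first ``split_fraction`` of the trajectory trains each candidate;
    validation counts are scored against the trained model with every
    probability floored at ``reg_eps / n`` (then column-renormalized), so
    transitions unseen in training remain finite.  The full empirical model
    is included as a baseline (label "full").
    """
    if not 0.0 < split_fraction < 1.0:
        raise ValidationError("split_fraction must be in (0, 1)")
    cut = int(len(traj) * split_fraction)
    if cut < 2 or len(traj) - cut < 2:
        raise ValidationError("trajectory too short for the requested split")
    n = traj.n_states
    train = DiscreteTrajectory(traj.labels[:cut], n, traj.lag)
    valid = DiscreteTrajectory(traj.labels[cut:], n, traj.lag)
    train_counts = count_transitions(train)
    valid_counts = count_transitions(valid)
    seen_train = set(np.unique(train.labels))
    seen_valid = set(np.unique(valid.labels))
    if not (seen_train & seen_valid):
        raise ValidationError("training and validation state sets are disjoint")
    if fitter not in _FITTERS:
        raise ValidationError(f"unknown fitter {fitter!r}")
    fit = _FITTERS[fitter]

    ss = np.random.SeedSequence(seed)
    Ks = list(Ks)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(Ks))]
    extra = {"refine": "sweeps"} if fitter == "dbmr" else {}
    results = []
    for K, s in zip(Ks, seeds):
        model, _ = fit(
            train_counts, K, restarts=restarts, seed=s, tol=tol, max_iter=max_iter,
            **extra,
        )
        P = _floored_probabilities(model, n, reg_eps)
        val_ll = _score_dense(valid_counts, P)
        results.append(
            CVResult(
                label=f"{fitter}-K{K}",
                K=K,
                train_log_likelihood=log_likelihood(train_counts, model),
                validation_log_likelihoods=(val_ll,),
                mean_validation=val_ll,
            )
        )
    full_op = empirical_estimator(train_counts)
    P = _floored_probabilities(full_op, n, reg_eps)
    val_ll = _score_dense(valid_counts, P)
    results.append(
        CVResult(
            label="full",
            K=n,
            train_log_likelihood=log_likelihood(train_counts, full_op),
            validation_log_likelihoods=(val_ll,),
            mean_validation=val_ll,
        )
    )
    return results


def best_k_by_validation(results: list[CVResult]) -> int:
    """K of the latent candidate with the highest mean validation score."""
    latent = [r for r in results if r.label != "full"]
    if not latent:
        raise ValidationError("no latent candidates in results")
    return max(latent, key=lambda r: r.mean_validation).K


# ---------------------------------------------------------------------------
# Bootstrap confidence envelopes
# ---------------------------------------------------------------------------

def bootstrap_measure(
    traj: DiscreteTrajectory,
    K: int,
    n_boot: int = 100,
    seed: int = 0,
    fitter: str = "dbmr",
    restarts: int = 3,
    quantiles: tuple = (0.025, 0.975),
) -> BootstrapResult:
    """Nonparametric bootstrap confidence envelopes for mu.

    Each replicate resamples the M observed transition pairs with
    replacement (the independent units of the likelihood), refits the
    latent model, and recomputes mu; states absent from a replicate get
    mu = 0 there.  Replicates with a reducible reduced operator are dropped
    and counted.  Returns per-state empirical quantile envelopes together
    with the full-data point estimate.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    if fitter not in _FITTERS:
        raise ValidationError(f"unknown fitter {fitter!r}")
    fit = _FITTERS[fitter]
    counts = count_transitions(traj)
    n = counts.n
    src = traj.labels[:-1]
    dst = traj.labels[1:]
    M = src.size

    ss = np.random.SeedSequence(seed)
    extra = {"refine": "sweeps"} if fitter == "dbmr" else {}
    fit_seed = int(ss.generate_state(1)[0] % (2**31))
    model, _ = fit(counts, K, restarts=restarts, seed=fit_seed, **extra)
    point, _ = latent_invariant_measure(model)

    rng = np.random.default_rng(ss.spawn(1)[0])
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_boot)]
    mus = []
    dropped = 0
    for b in range(n_boot):
        pick = rng.integers(0, M, size=M)
        mat = sp.coo_matrix(
            (np.ones(M, dtype=np.int64), (dst[pick], src[pick])), shape=(n, n)
        ).tocsr()
        try:
            m, _ = fit(TransitionCounts(mat), K, restarts=restarts, seed=rep_seeds[b], **extra)
            mu, _ = latent_invariant_measure(m)
        except (ReducibleOperatorError, NumericalError):
            dropped += 1
            continue
        mus.append(mu.vector)
    if not mus:
        raise NumericalError("every bootstrap replicate was reducible")
    stack = np.vstack(mus)
    lo = np.quantile(stack, quantiles[0], axis=0)
    hi = np.quantile(stack, quantiles[1], axis=0)
    return BootstrapResult(
        lower=lo,
        upper=hi,
        point=point.vector,
        n_replicates=len(mus),
        n_dropped=dropped,
        quantiles=quantiles,
    )
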