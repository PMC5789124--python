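"""Synthetic data generators: Lorenz-63 trajectories, Markov-chain samplers
and planted latent models.

These are the package's study conditions, not mere fixtures: the Lorenz
benchmark uses the standard chaotic parameter setting (sigma=10, rho=28,
beta=8/3) integrated with classical fixed-step RK4 at dt=1e-3, sampled
after a 10^4-step burn-in to land on the attractor.  The chain samplers
realize the master equation generatively, and ``make_planted_model`` builds
ground-truth latent factorizations for parameter-recovery and K-selection
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, ValidationError
from .latent import LatentModel
from .ulam import DiscreteTrajectory, TransferOperator, invariant_measure_full


@dataclass(frozen=True)
class LorenzParams:
    """Integration settings for the Lorenz-63 system.

    The returned samples are spaced tau = sample_stride * dt apart;
    defaults produce 2x10^5 samples at tau = 1e-3 from the attractor.
    """

    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    dt: float = 1e-3
    sample_stride: int = 1
    n_steps: int = 210_000
    initial: tuple = (1.0, 1.0, 1.0)
    burn_in: int = 10_000

    def __post_init__(self):
        if not self.dt > 0:
            raise ValidationError("dt must be positive")
        if self.sample_stride < 1:
            raise ValidationError("sample_stride must be >= 1")
        if not self.n_steps > self.burn_in >= 0:
            raise ValidationError("need n_steps > burn_in >= 0")
        if len(self.initial) != 3:
            raise ValidationError("initial state must be a 3-vector")


def simulate_lorenz(params: LorenzParams) -> np.ndarray:
    """Integrate the Lorenz-63 ODEs with classical 4th-order Runge-Kutta.

        dx/dt = sigma (y - x)
        dy/dt = x (rho - z) - y
        dz/dt = x y - beta z

    Discards ``burn_in`` steps, then returns every ``sample_stride``-th
    state as an (m, 3) array.  Deterministic given params.
    """
    s, r, b = params.sigma, params.rho, params.beta
    dt = params.dt
    x, y, z = (float(v) for v in params.initial)
    m = (params.n_steps - params.burn_in) // params.sample_stride
    out = np.empty((m, 3))
    w = 0
    # scalar-float RK4: substantially faster than per-step array arithmetic
    for step in range(params.n_steps):
        k1x = s * (y - x); k1y = x * (r - z) - y; k1z = x * y - b * z
        ax = x + 0.5 * dt * k1x; ay = y + 0.5 * dt * k1y; az = z + 0.5 * dt * k1z
        k2x = s * (ay - ax); k2y = ax * (r - az) - ay; k2z = ax * ay - b * az
        bx = x + 0.5 * dt * k2x; by = y + 0.5 * dt * k2y; bz = z + 0.5 * dt * k2z
        k3x = s * (by - bx); k3y = bx * (r - bz) - by; k3z = bx * by - b * bz
        cx = x + dt * k3x; cy = y + dt * k3y; cz = z + dt * k3z
        k4x = s * (cy - cx); k4y = cx * (r - cz) - cy; k4z = cx * cy - b * cz
        x += dt * (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0
        y += dt * (k1y + 2 * k2y + 2 * k3y + k4y) / 6.0
        z += dt * (k1z + 2 * k2z + 2 * k3z + k4z) / 6.0
        done = step + 1  # completed integration steps
        if done > params.burn_in and (done - params.burn_in) % params.sample_stride == 0:
            out[w] = (x, y, z)
            w += 1
        if not (abs(x) < 1e6 and abs(y) < 1e6 and abs(z) < 1e6):
            raise NumericalError(f"non-finite or diverging state at step {step}")
    return out[:w]


def _column_cumsums(matrix) -> np.ndarray:
    dense = np.asarray(matrix.todense() if hasattr(matrix, "todense") else matrix, dtype=float)
    return np.cumsum(dense, axis=0)


def sample_markov_chain(
    op: TransferOperator,
    length: int,
    start=0,
    seed: int = 0,
) -> DiscreteTrajectory:
    """Sample a trajectory from a transfer operator.

    ``start`` is a state index or "stationary" (X(0) drawn from the
    invariant measure).  Deterministic given ``seed``.
    """
    if length < 1:
        raise ValidationError("length must be >= 1")
    n = op.n
    rng = np.random.default_rng(seed)
    cum = _column_cumsums(op.matrix)
    labels = np.empty(length, dtype=np.int64)
    if start == "stationary":
        mu, _ = invariant_measure_full(op)
        state = int(np.searchsorted(np.cumsum(mu.vector), rng.random()))
    else:
        state = int(start)
        if not 0 <= state < n:
            raise ValidationError(f"start state {state} outside [0, {n})")
    u = rng.random(length)
    for t in range(length):
        labels[t] = state
        if t + 1 < length:
            if op.undefined[state]:
                raise ValidationError(
                    f"reached undefined column {state}; cannot continue sampling"
                )
            state = int(np.searchsorted(cum[:, state], u[t]))
            state = min(state, n - 1)
    return DiscreteTrajectory(labels, n_states=n, lag=1.0)


def sample_latent_chain(
    model: LatentModel,
    length: int,
    start: int = 0,
    seed: int = 0,
) -> DiscreteTrajectory:
    """Sample the two-stage generative process of the latent factorization:
    from X(s)=j draw the latent state k from column j of Gamma, then
    X(s+1)=i from column k of lam.  The induced chain has transition matrix
    lam Gamma.  Deterministic given ``seed``."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    n, K = model.n, model.K
    if not 0 <= start < n:
        raise ValidationError(f"start state {start} outside [0, {n})")
    rng = np.random.default_rng(seed)
    lam_cum = np.cumsum(model.lam, axis=0)
    labels = np.empty(length, dtype=np.int64)
    state = int(start)
    if model.hard:
        assign = model.assignments
        u = rng.random(length)
        for t in range(length):
            labels[t] = state
            if t + 1 < length:
                k = assign[state]
                state = min(int(np.searchsorted(lam_cum[:, k], u[t])), n - 1)
    else:
        gamma_cum = np.cumsum(model.gamma, axis=0)
        ug = rng.random(length)
        ul = rng.random(length)
        for t in range(length):
            labels[t] = state
            if t + 1 < length:
                k = min(int(np.searchsorted(gamma_cum[:, state], ug[t])), K - 1)
                state = min(int(np.searchsorted(lam_cum[:, k], ul[t])), n - 1)
    return DiscreteTrajectory(labels, n_states=n, lag=1.0)


def make_planted_model(
    n: int,
    K: int,
    separation: float = 0.9,
    seed: int = 0,
) -> LatentModel:
    """Ground-truth hard latent model with K near-equal state groups.

    lam column k places mass ``separation`` uniformly on group k and leaks
    the remaining ``1 - separation`` uniformly on the other states; Gamma is
    hard, sending every state of group g to latent state perm[g] for a
    seeded permutation of the K latent labels (a row-permuted dominant-
    diagonal template).  ``separation=1`` gives disjoint lam supports.
    """
    if not 1 <= K <= n:
        raise ValidationError(f"need 1 <= K <= n (got K={K}, n={n})")
    if not 0.0 < separation <= 1.0:
        raise ValidationError("separation must be in (0, 1]")
    rng = np.random.default_rng(seed)
    group = np.zeros(n, dtype=np.int64)
    for g, members in enumerate(np.array_split(np.arange(n), K)):
        group[members] = g
    lam = np.zeros((n, K))
    for k in range(K):
        members = group == k
        size = int(members.sum())
        if size == n:
            lam[:, k] = 1.0 / n
            continue
        lam[members, k] = separation / size
        lam[~members, k] = (1.0 - separation) / (n - size)
        if separation == 1.0:
            lam[~members, k] = 0.0
    lam /= lam.sum(axis=0)
    perm = rng.permutation(K)
    gamma = np.zeros((K, n))
    gamma[perm[group], np.arange(n)] = 1.0
    return LatentModel(gamma, lam, hard=True)


def make_trap_chain(
    n_recurrent: int = 29,
    K: int = 3,
    length: int = 5000,
    trap_fraction: float = 0.01,
    separation: float = 0.9,
    seed: int = 0,
) -> DiscreteTrajectory:
    """A trajectory over n_recurrent + 1 states whose last state is a
    one-way trap occupying ``trap_fraction`` of the frames.

    The recurrent part is sampled from a planted latent chain; the
    trajectory then makes a single irreversible transition into the trap
    and self-loops there for the rest of its length.  Mimics absorbing
    states in under-sampled data, which inflate the empirical-estimator
    invariant measure.
    """
    n_trap = max(1, int(round(length * trap_fraction)))
    n_main = length - n_trap
    if n_main < 2:
        raise ValidationError("length too short for the requested trap fraction")
    planted = make_planted_model(n_recurrent, K, separation=separation, seed=seed)
    main = sample_latent_chain(planted, n_main, start=0, seed=seed)
    trap = np.full(n_trap, n_recurrent, dtype=np.int64)
    labels = np.concatenate([main.labels, trap])
    return DiscreteTrajectory(labels, n_states=n_recurrent + 1, lag=1.0)
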