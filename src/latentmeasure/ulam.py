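"""Ulam's approach: grid discretization, transition counting, the empirical
frequency estimator and the standard (full-operator) invariant measure.

The pipeline discretizes a continuous trajectory into boxes, estimates the
column-stochastic transfer operator

    Lambda[i, j] = P[X(s + tau) = x(i) | X(s) = x(j)]

by column-normalizing the observed transition counts, and extracts the
invariant measure mu as the eigenvector of Lambda for eigenvalue 1.

Conventions (used throughout the package):

* state labels are 0-based integers;
* matrices are destination-row / source-column and column-stochastic;
* grid linearization is row-major with the first coordinate varying slowest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .errors import NumericalError, ReducibleOperatorError, ValidationError

logger = logging.getLogger(__name__)

_STOCHASTIC_ATOL = 1e-12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """A uniform rectangular box grid over a d-dimensional phase space.

    Each dimension is split into ``bins[k]`` equal half-open bins
    ``[edge, next_edge)``; the last bin of each dimension is closed so that
    the upper bound itself is representable.
    """

    lower: np.ndarray
    upper: np.ndarray
    bins: np.ndarray

    def __post_init__(self):
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        bins = np.atleast_1d(np.asarray(self.bins, dtype=int))
        if not (lower.shape == upper.shape == bins.shape) or lower.ndim != 1:
            raise ValidationError("lower, upper and bins must be 1-D and of equal length")
        if np.any(upper <= lower):
            raise ValidationError("upper must exceed lower in every dimension")
        if np.any(bins < 1):
            raise ValidationError("bin counts must be >= 1")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "bins", bins)

    @property
    def ndim(self) -> int:
        return self.lower.shape[0]

    @property
    def n_boxes(self) -> int:
        return int(np.prod(self.bins))

    @classmethod
    def from_data(cls, points: np.ndarray, bins, padding: float = 0.01) -> "GridSpec":
        """Data-driven bounding box with symmetric relative padding."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        lo = points.min(axis=0)
        hi = points.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        bins = np.broadcast_to(np.atleast_1d(np.asarray(bins, dtype=int)), lo.shape).copy()
        return cls(lo - padding * span, hi + padding * span, bins)

    def multi_index(self, points: np.ndarray) -> tuple[np.ndarray, int]:
        """Per-dimension bin indices; returns (indices (m, d), #clamped points)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[1] != self.ndim:
            raise ValidationError(
                f"points have dimension {points.shape[1]}, grid has {self.ndim}"
            )
        width = (self.upper - self.lower) / self.bins
        raw = np.floor((points - self.lower) / width).astype(np.int64)
        clamped = int(np.count_nonzero((raw < 0) | (raw > self.bins - 1)))
        idx = np.clip(raw, 0, self.bins - 1)
        return idx, clamped

    def box_centers(self, flat_indices: np.ndarray) -> np.ndarray:
        """Center coordinates of the boxes with the given linearized indices."""
        flat_indices = np.asarray(flat_indices, dtype=np.int64)
        multi = np.unravel_index(flat_indices, tuple(self.bins))
        width = (self.upper - self.lower) / self.bins
        return np.stack(
            [self.lower[d] + (multi[d] + 0.5) * width[d] for d in range(self.ndim)],
            axis=-1,
        )


@dataclass(frozen=True)
class DiscreteTrajectory:
    """A categorical time series X(0), X(tau), ..., with states in [0, n)."""

    labels: np.ndarray
    n_states: int
    lag: float = 1.0

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64).ravel()
        if labels.size < 1:
            raise ValidationError("trajectory must contain at least one label")
        if self.n_states < 1:
            raise ValidationError("n_states must be >= 1")
        if labels.min() < 0 or labels.max() >= self.n_states:
            raise ValidationError(
                f"labels must lie in [0, {self.n_states}); got range "
                f"[{labels.min()}, {labels.max()}]"
            )
        if not self.lag > 0:
            raise ValidationError("lag must be positive")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class TransitionCounts:
    """Sparse transition count matrix, N[i, j] = #(j -> i observed)."""

    matrix: sp.csr_matrix

    def __post_init__(self):
        m = sp.csr_matrix(self.matrix)
        if m.shape[0] != m.shape[1]:
            raise ValidationError("count matrix must be square")
        if m.nnz and m.data.min() < 0:
            raise ValidationError("transition counts must be nonnegative")
        m = m.astype(np.int64)
        m.eliminate_zeros()
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def pairs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(dest, source, count) arrays of the nonzero entries."""
        coo = self.matrix.tocoo()
        return coo.row, coo.col, coo.data


@dataclass(frozen=True)
class TransferOperator:
    """Column-stochastic transfer operator with a mask of undefined columns.

    Columns whose source state was never observed carry no information; they
    are filled by a policy (uniform or self-loop) and flagged in
    ``undefined`` so downstream code can refuse to use them.
    """

    matrix: sp.csc_matrix
    undefined: np.ndarray = None

    def __post_init__(self):
        m = sp.csc_matrix(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1]:
            raise ValidationError("transfer operator must be square")
        und = self.undefined
        if und is None:
            und = np.zeros(m.shape[1], dtype=bool)
        und = np.asarray(und, dtype=bool).ravel()
        if und.size != m.shape[1]:
            raise ValidationError("undefined mask length must equal n")
        if m.nnz and m.data.min() < -_STOCHASTIC_ATOL:
            raise ValidationError("transfer operator entries must be nonnegative")
        colsums = np.asarray(m.sum(axis=0)).ravel()
        defined = ~und
        if np.any(np.abs(colsums[defined] - 1.0) > 1e-9):
            worst = np.abs(colsums[defined] - 1.0).max()
            raise ValidationError(
                f"defined columns must sum to 1 (worst deviation {worst:.3g})"
            )
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "undefined", und)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


@dataclass(frozen=True)
class InvariantMeasure:
    """A stationary probability vector mu with mu = Lambda mu."""

    vector: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float).ravel()
        if v.size < 1:
            raise ValidationError("measure must be non-empty")
        if v.min() < -_STOCHASTIC_ATOL:
            raise ValidationError("measure entries must be nonnegative")
        v = np.clip(v, 0.0, None)
        s = v.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValidationError("measure must have positive finite mass")
        if abs(s - 1.0) > 1e-9:
            raise ValidationError(f"measure must sum to 1 (got {s!r})")
        object.__setattr__(self, "vector", v / s)

    @property
    def n(self) -> int:
        return self.vector.size


@dataclass(frozen=True)
class MeasureDiagnostics:
    method: str
    residual: float
    iterations: int = 0
    spectral_gap: float | None = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def discretize(
    points,
    grid: GridSpec,
    compact: bool = False,
    lag: float = 1.0,
) -> tuple[DiscreteTrajectory, np.ndarray]:
    """Map continuous points to linearized box labels.

    Points outside the grid bounds are clamped into the nearest boundary bin
    (with a logged warning) — trajectories integrated with adaptive steps can
    graze a bounding box estimated from the data itself.

    Returns
    -------
    traj : DiscreteTrajectory
    label_to_box : ndarray
        ``label_to_box[label]`` is the linearized grid box index of each
        state label.  Identity when ``compact`` is False; with ``compact``
        only visited boxes receive labels ``0..n_visited-1``.
    """
    idx, clamped = grid.multi_index(points)
    if clamped:
        logger.warning("%d point(s) outside grid bounds clamped into boundary bins", clamped)
    flat = np.ravel_multi_index(tuple(idx.T), tuple(grid.bins))  # C order: first dim slowest
    if compact:
        visited, labels = np.unique(flat, return_inverse=True)
        traj = DiscreteTrajectory(labels, n_states=visited.size, lag=lag)
        return traj, visited
    traj = DiscreteTrajectory(flat, n_states=grid.n_boxes, lag=lag)
    return traj, np.arange(grid.n_boxes, dtype=np.int64)


def count_transitions(traj: DiscreteTrajectory, lag_multiple: int = 1) -> TransitionCounts:
    """Count observed transitions N[i, j] = #{s : X(s + L*tau)=i, X(s)=j}.

    Sliding window of stride 1, so ``total == len(traj) - lag_multiple``.
    """
    if lag_multiple < 1:
        raise ValidationError("lag_multiple must be a positive integer")
    if len(traj) <= lag_multiple:
        raise ValidationError(
            f"trajectory of length {len(traj)} too short for lag multiple {lag_multiple}"
        )
    src = traj.labels[:-lag_multiple]
    dst = traj.labels[lag_multiple:]
    n = traj.n_states
    mat = sp.coo_matrix(
        (np.ones(src.size, dtype=np.int64), (dst, src)), shape=(n, n)
    ).tocsr()
    return TransitionCounts(mat)


def empirical_estimator(
    counts: TransitionCounts, undefined_policy: str = "uniform"
) -> TransferOperator:
    """Maximum-likelihood transfer operator: column-normalized counts.

    Zero-count source columns are undefined; they are filled uniformly
    (default) or with a self-loop and flagged in the ``undefined`` mask.
    """
    if counts.total == 0:
        raise ValidationError("cannot estimate a transfer operator from all-zero counts")
    if undefined_policy not in ("uniform", "self-loop"):
        raise ValidationError(f"unknown undefined-column policy {undefined_policy!r}")
    n = counts.n
    colsums = np.asarray(counts.matrix.sum(axis=0)).ravel().astype(float)
    undefined = colsums == 0
    inv = np.where(undefined, 0.0, 1.0 / np.where(undefined, 1.0, colsums))
    mat = (counts.matrix.astype(float) @ sp.diags(inv)).tolil()
    for j in np.flatnonzero(undefined):
        if undefined_policy == "uniform":
            mat[:, j] = 1.0 / n
        else:
            mat[j, j] = 1.0
    return TransferOperator(mat.tocsc(), undefined)


def _closed_classes(matrix: sp.spmatrix) -> list[np.ndarray]:
    """Closed (no-exit) strongly connected classes of the support graph.

    ``matrix[i, j] > 0`` encodes the edge j -> i, so the csgraph adjacency
    (which reads G[a, b] as a -> b) is the transpose of the support.
    """
    support = sp.csr_matrix((matrix != 0).T)
    n_comp, comp = connected_components(support, directed=True, connection="strong")
    coo = support.tocoo()
    has_exit = np.zeros(n_comp, dtype=bool)
    cross = comp[coo.row] != comp[coo.col]
    has_exit[np.unique(comp[coo.row[cross]])] = True
    return [np.flatnonzero(comp == c) for c in range(n_comp) if not has_exit[c]]


def invariant_measure_full(
    op: TransferOperator,
    method: str = "eig",
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> tuple[InvariantMeasure, MeasureDiagnostics]:
    """Invariant measure of a full transfer operator.

    ``method="eig"`` solves the dominant eigenpair (dense for small n,
    sparse Lanczos otherwise); ``method="power"`` iterates mu <- Lambda mu
    from the uniform vector until the successive-iterate l1 change drops
    below ``tol``.

    Raises
    ------
    ReducibleOperatorError
        if the chain has more than one closed communicating class (the
        eigenvalue-1 eigenspace is then degenerate and any returned vector
        would silently pick one basin).
    """
    if op.undefined.any():
        raise ValidationError(
            f"operator has {int(op.undefined.sum())} undefined column(s); "
            "an invariant measure is not meaningful"
        )
    if method not in ("eig", "power"):
        raise ValidationError(f"unknown method {method!r}")
    n = op.n
    closed = _closed_classes(op.matrix)
    if len(closed) > 1:
        raise ReducibleOperatorError(
            f"operator is reducible: {len(closed)} disconnected closed state sets "
            f"{[b.tolist() for b in closed]}",
            blocks=[b.tolist() for b in closed],
        )

    gap = None
    if method == "power":
        mu = np.full(n, 1.0 / n)
        mat = op.matrix
        for it in range(1, max_iter + 1):
            nxt = mat @ mu
            nxt /= nxt.sum()
            change = np.abs(nxt - mu).sum()
            mu = nxt
            if change < tol:
                iterations = it
                break
        else:
            residual = float(np.abs(mat @ mu - mu).sum())
            raise NumericalError(
                f"power iteration did not converge in {max_iter} iterations "
                f"(l1 residual {residual:.3g})"
            )
    else:
        iterations = 0
        if n <= 300:
            vals, vecs = np.linalg.eig(op.toarray())
            order = np.argsort(-np.abs(vals))
            vals, vecs = vals[order], vecs[:, order]
            close = np.abs(vals - 1.0) < 1e-9
            if close.sum() > 1:
                raise ReducibleOperatorError(
                    "dominant eigenvalue 1 has multiplicity "
                    f"{int(close.sum())} within tolerance",
                    blocks=[b.tolist() for b in closed],
                )
            if n > 1:
                gap = float(1.0 - np.abs(vals[1]))
            k = int(np.argmin(np.abs(vals - 1.0)))
            mu = np.real(vecs[:, k])
        else:
            v0 = np.full(n, 1.0 / n)
            vals, vecs = sp.linalg.eigs(op.matrix, k=2, which="LM", v0=v0)
            order = np.argsort(-np.abs(vals))
            vals, vecs = vals[order], vecs[:, order]
            if np.abs(vals[1] - 1.0) < 1e-9:
                raise ReducibleOperatorError(
                    "dominant eigenvalue 1 has multiplicity > 1 within tolerance",
                    blocks=[b.tolist() for b in closed],
                )
            gap = float(1.0 - np.abs(vals[1]))
            k = int(np.argmin(np.abs(vals - 1.0)))
            mu = np.real(vecs[:, k])
        if mu.sum() < 0:
            mu = -mu
        neg_floor = max(tol, 1e-10)
        if mu.min() < -neg_floor * max(1.0, np.abs(mu).max()):
            raise NumericalError(
                f"dominant eigenvector has significant negative entries "
                f"(min {mu.min():.3g}); chain may be ill-conditioned"
            )
        mu = np.clip(mu, 0.0, None)
        mu /= mu.sum()
        if gap is not None and gap < 1e-9:
            logger.warning("spectral gap %.3g is below 1e-9; measure may be unstable", gap)

    residual = float(np.abs(op.matrix @ mu - mu).sum())
    return InvariantMeasure(mu), MeasureDiagnostics(
        method=method, residual=residual, iterations=iterations, spectral_gap=gap
    )
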