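"""Plain-text file formats: trajectories, counts, measures and models.

Everything on disk is human-inspectable — integer labels one per line,
Matrix Market for matrices, TSV for tables, JSON for manifests — so runs
are diffable across platforms.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__
from .errors import ParseError, ValidationError
from .latent import LatentModel
from .selection import CVResult, ModelScore
from .ulam import DiscreteTrajectory, InvariantMeasure, TransitionCounts


# ---------------------------------------------------------------------------
# Discrete trajectories: one integer label per line, optional header
#   # n=<n> lag=<tau>
# ---------------------------------------------------------------------------

def write_discrete_trajectory(traj: DiscreteTrajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n={traj.n_states} lag={traj.lag!r}\n")
        fh.write("\n".join(str(int(v)) for v in traj.labels))
        fh.write("\n")


def read_discrete_trajectory(path) -> DiscreteTrajectory:
    n = None
    lag = 1.0
    labels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].replace(",", " ").split():
                    if token.startswith("n="):
                        n = int(token[2:])
                    elif token.startswith("lag="):
                        lag = float(token[4:])
                continue
            token = line.split(",")[0].strip()
            try:
                labels.append(int(token))
            except ValueError:
                raise ParseError(f"non-integer state label {token!r}", line=lineno)
    if not labels:
        raise ParseError(f"no state labels found in {path}")
    arr = np.asarray(labels, dtype=np.int64)
    if n is None:
        n = int(arr.max()) + 1
    if arr.max() >= n:
        raise ValidationError(
            f"label {int(arr.max())} out of range for declared n={n}"
        )
    return DiscreteTrajectory(arr, n_states=n, lag=lag)


# ---------------------------------------------------------------------------
# Continuous trajectories: CSV/TSV, one frame per row
# ---------------------------------------------------------------------------

def read_continuous_trajectory(path) -> np.ndarray:
    """CSV or TSV of real-valued rows; an optional single header row and
    '#' comment lines are skipped."""
    # explicit delimiter detection: the csv sniffer misreads 1-column files
    sep = r"\s+"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                sep = "\t"
            elif "," in line:
                sep = ","
            break
    df = pd.read_csv(path, sep=sep, engine="python", comment="#", header=None)
    first = df.iloc[0]
    try:
        first.astype(float)
        skip = 0
    except (ValueError, TypeError):
        skip = 1
    try:
        data = df.iloc[skip:].astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ParseError(f"non-numeric value in {path}: {exc}")
    if data.size == 0:
        raise ParseError(f"no data rows in {path}")
    return data


def write_continuous_trajectory(points: np.ndarray, path, dt: float | None = None) -> None:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    cols = {"t": np.arange(points.shape[0]) * (dt if dt else 1.0)}
    names = ["x", "y", "z"] + [f"c{d}" for d in range(3, points.shape[1])]
    for d in range(points.shape[1]):
        cols[names[d]] = points[:, d]
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Counts: Matrix Market coordinate, integer field, 1-based on disk
# ---------------------------------------------------------------------------

def write_counts_mtx(counts: TransitionCounts, path) -> None:
    scipy.io.mmwrite(str(path), counts.matrix, field="integer")


def read_counts_mtx(path) -> TransitionCounts:
    rows, cols, entries, fmt, fieldtype, symm = scipy.io.mminfo(str(path))
    if fieldtype != "integer":
        raise ValidationError(
            f"count matrices must use the integer field (got {fieldtype!r})"
        )
    if rows != cols:
        raise ValidationError(f"count matrix must be square (got {rows}x{cols})")
    mat = sp.csr_matrix(scipy.io.mmread(str(path)))
    return TransitionCounts(mat)


# ---------------------------------------------------------------------------
# Measures: two-column TSV (state_label, probability)
# ---------------------------------------------------------------------------

def write_measure(measure: InvariantMeasure, path) -> None:
    pd.DataFrame(
        {"state": np.arange(measure.n), "probability": measure.vector}
    ).to_csv(path, sep="\t", index=False)


def read_measure(path) -> InvariantMeasure:
    df = pd.read_csv(path, sep="\t")
    order = np.argsort(df["state"].to_numpy())
    return InvariantMeasure(df["probability"].to_numpy()[order])


# ---------------------------------------------------------------------------
# Models: Matrix Market factors + JSON manifest
# ---------------------------------------------------------------------------

def save_model(model: LatentModel, directory, provenance: dict | None = None) -> None:
    """Store gamma and lam as real Matrix Market files plus manifest.json
    with shape, the hard flag and optional fit provenance (seed, fitter,
    log-likelihood)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(directory / "gamma.mtx"), sp.coo_matrix(model.gamma), field="real", precision=17
    )
    scipy.io.mmwrite(
        str(directory / "lambda.mtx"), sp.coo_matrix(model.lam), field="real", precision=17
    )
    manifest = {
        "K": model.K,
        "n": model.n,
        "hard": model.hard,
        "format_version": 1,
        "package_version": __version__,
    }
    if provenance:
        manifest["provenance"] = provenance
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def load_model(directory) -> tuple[LatentModel, dict]:
    """Load a saved model; invariants are re-validated, so a tampered file
    (e.g. a column sum far from 1) fails here."""
    directory = Path(directory)
    try:
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
    except FileNotFoundError:
        raise ValidationError(f"no manifest.json in {directory}")
    gamma = np.asarray(scipy.io.mmread(str(directory / "gamma.mtx")).todense(), dtype=float)
    lam = np.asarray(scipy.io.mmread(str(directory / "lambda.mtx")).todense(), dtype=float)
    K, n = int(manifest["K"]), int(manifest["n"])
    if gamma.shape != (K, n) or lam.shape != (n, K):
        raise ValidationError(
            f"factor shapes {gamma.shape}/{lam.shape} disagree with manifest (K={K}, n={n})"
        )
    model = LatentModel(gamma, lam, hard=bool(manifest.get("hard", False)))
    return model, manifest


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_scores(scores: list[ModelScore], path) -> None:
    pd.DataFrame(
        {
            "label": [s.label for s in scores],
            "K": [s.K for s in scores],
            "loglik": [s.log_likelihood for s in scores],
            "p": [s.n_parameters for s in scores],
            "AIC": [s.aic for s in scores],
            "BIC": [s.bic for s in scores],
            "M": [s.sample_size for s in scores],
        }
    ).to_csv(path, sep="\t", index=False)


def write_cv(results: list[CVResult], path) -> None:
    rows = []
    for r in results:
        for fold, vll in enumerate(r.validation_log_likelihoods):
            rows.append(
                {
                    "label": r.label,
                    "K": r.K,
                    "fold": fold,
                    "train_ll": r.train_log_likelihood,
                    "val_ll": vll,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
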