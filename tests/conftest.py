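"""Shared fixtures: the Lorenz benchmark pipeline and a planted latent
chain, built once per session because several suites reuse them."""

import numpy as np
import pytest

import latentmeasure as lm

LORENZ_SEED = 0
PLANTED_SEED = 5
PLANTED_CHAIN_SEED = 11
PLANTED_N, PLANTED_K = 60, 3
PLANTED_LENGTH = 200_001  # 2e5 observed transitions


@pytest.fixture(scope="session")
def lorenz_pipeline():
    """Lorenz-63 trajectory discretized on a 20x20x20 grid (compact labels)."""
    points = lm.simulate_lorenz(lm.LorenzParams())
    grid = lm.GridSpec.from_data(points, [20, 20, 20], padding=0.01)
    traj, boxes = lm.discretize(points, grid, compact=True)
    counts = lm.count_transitions(traj)
    return {
        "points": points,
        "grid": grid,
        "traj": traj,
        "boxes": boxes,
        "counts": counts,
    }


@pytest.fixture(scope="session")
def lorenz_k2_fit(lorenz_pipeline):
    model, diag = lm.fit_dbmr(
        lorenz_pipeline["counts"], K=2, restarts=10, seed=LORENZ_SEED
    )
    return model, diag


@pytest.fixture(scope="session")
def planted_instance():
    """Planted 3-group latent chain over 60 states, 2e5 transitions."""
    model = lm.make_planted_model(
        PLANTED_N, PLANTED_K, separation=0.9, seed=PLANTED_SEED
    )
    traj = lm.sample_latent_chain(
        model, PLANTED_LENGTH, start=0, seed=PLANTED_CHAIN_SEED
    )
    counts = lm.count_transitions(traj)
    truth = np.zeros(PLANTED_N, dtype=int)
    for g, members in enumerate(np.array_split(np.arange(PLANTED_N), PLANTED_K)):
        truth[members] = g
    return {"model": model, "traj": traj, "counts": counts, "truth": truth}


@pytest.fixture(scope="session")
def planted_k_fits(planted_instance):
    """DBMR fits for K = 1..6 on the planted chain, with diagnostics."""
    counts = planted_instance["counts"]
    out = {}
    for K in range(1, 7):
        out[K] = lm.fit_dbmr(counts, K, restarts=10, seed=K)
    return out


def assert_monotone_trace(trace, tol=1e-9):
    trace = np.asarray(trace, dtype=float)
    assert trace.size >= 1
    if trace.size > 1:
        drops = np.diff(trace)
        assert drops.min() >= -tol * np.maximum(1.0, np.abs(trace[:-1])).max()
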