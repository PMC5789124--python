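"""The latent factorization: DBMR and PLSA fitters, the reduced operator,
the Perron-Frobenius lift and the spectral components."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

import latentmeasure as lm
from latentmeasure.errors import (
    NumericalError,
    ReducibleOperatorError,
    ValidationError,
)
from latentmeasure.latent import _aggregate, _closed_ll

from conftest import assert_monotone_trace


def _block_diagonal_counts():
    """Two 3-state blocks with within-block transitions only."""
    rng = np.random.default_rng(12)
    mat = np.zeros((6, 6), dtype=int)
    mat[:3, :3] = rng.integers(5, 40, size=(3, 3))
    mat[3:, 3:] = rng.integers(5, 40, size=(3, 3))
    return lm.TransitionCounts(sp.csr_matrix(mat))


def _brute_force_best_assignment(counts, K):
    """Exhaustive search over all K^n hard assignments (small n only)."""
    N = counts.matrix.tocsc().astype(float)
    n = counts.n
    best = (-np.inf, None)
    for assign in itertools.product(range(K), repeat=n):
        assign = np.asarray(assign)
        if len(set(assign.tolist())) < K:
            continue
        S = _aggregate(N, assign, K)
        ll = _closed_ll(S, S.sum(axis=0))
        if ll > best[0]:
            best = (ll, assign)
    return best


class TestFitDBMR:
    def test_recovers_block_structure_and_matches_exhaustive_optimum(self):
        counts = _block_diagonal_counts()
        ll_star, assign_star = _brute_force_best_assignment(counts, 2)
        model, diag = lm.fit_dbmr(counts, 2, restarts=8, seed=0)
        assert diag.log_likelihood == pytest.approx(ll_star, rel=1e-12)
        found = model.assignments
        same = (found == assign_star).all() or (found == 1 - assign_star).all()
        assert same
        assert model.hard

    def test_k1_closed_form_is_destination_marginal(self):
        counts = _block_diagonal_counts()
        model, _ = lm.fit_dbmr(counts, 1)
        assert np.allclose(model.gamma, np.ones((1, 6)))
        marginal = np.asarray(counts.matrix.sum(axis=1)).ravel() / counts.total
        assert np.allclose(model.lam[:, 0], marginal, atol=1e-14)

    def test_k_equals_n_identity_init_reproduces_empirical_estimator(self):
        counts = _block_diagonal_counts()
        n = counts.n
        model, diag = lm.fit_dbmr(counts, n, init=np.arange(n))
        full = lm.empirical_estimator(counts)
        ll_full = lm.log_likelihood(counts, full)
        assert diag.log_likelihood == pytest.approx(ll_full, rel=1e-12)

    def test_invalid_k_rejected(self):
        counts = _block_diagonal_counts()
        with pytest.raises(ValidationError):
            lm.fit_dbmr(counts, 7)
        with pytest.raises(ValidationError):
            lm.fit_dbmr(counts, 0)

    def test_deterministic_given_seed(self):
        counts = _block_diagonal_counts()
        m1, _ = lm.fit_dbmr(counts, 2, seed=33)
        m2, _ = lm.fit_dbmr(counts, 2, seed=33)
        assert np.array_equal(m1.gamma, m2.gamma)
        assert np.array_equal(m1.lam, m2.lam)


class TestFitPLSA:
    def test_concentrates_on_blocks(self):
        counts = _block_diagonal_counts()
        model, _ = lm.fit_plsa(counts, 2, restarts=5, seed=1)
        # each source column's gamma should pile >= 0.99 on its block's state
        peak = model.gamma.max(axis=0)
        assert (peak >= 0.99).all()
        block_of = model.gamma.argmax(axis=0)
        assert len(set(block_of[:3].tolist())) == 1
        assert len(set(block_of[3:].tolist())) == 1
        assert block_of[0] != block_of[3]

    def test_k1_matches_dbmr(self):
        counts = _block_diagonal_counts()
        soft, _ = lm.fit_plsa(counts, 1, restarts=2, seed=0)
        hard, _ = lm.fit_dbmr(counts, 1)
        assert np.allclose(soft.lam, hard.lam, atol=1e-9)

    def test_likelihood_trace_is_monotone(self):
        counts = _block_diagonal_counts()
        for seed in (0, 1, 2):
            _, diag = lm.fit_plsa(counts, 3, restarts=2, seed=seed)
            assert_monotone_trace(diag.trace)


class TestReducedOperator:
    def test_k1_reduces_to_unit_scalar(self):
        model, _ = lm.fit_dbmr(_block_diagonal_counts(), 1)
        assert np.allclose(lm.reduced_operator(model).matrix, [[1.0]])

    def test_identity_aggregation_returns_full_operator(self):
        counts = _block_diagonal_counts()
        full = lm.empirical_estimator(counts).toarray()
        model = lm.LatentModel(np.eye(6), full)
        assert np.allclose(lm.reduced_operator(model).matrix, full)

    def test_hand_product_two_by_three(self):
        gamma = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        lam = np.array([[0.5, 0.0], [0.5, 0.0], [0.0, 1.0]])
        model = lm.LatentModel(gamma, lam, hard=True)
        assert np.allclose(lm.reduced_operator(model).matrix, np.eye(2))

    def test_disconnected_latent_blocks_make_measure_ill_posed(self):
        gamma = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        lam = np.array([[0.5, 0.0], [0.5, 0.0], [0.0, 1.0]])
        model = lm.LatentModel(gamma, lam, hard=True)
        with pytest.raises(ReducibleOperatorError):
            lm.latent_invariant_measure(model)


def _random_model(rng, n, K):
    lam = rng.uniform(0.01, 1.0, size=(n, K))
    gamma = rng.uniform(0.01, 1.0, size=(K, n))
    return lm.LatentModel(gamma / gamma.sum(axis=0), lam / lam.sum(axis=0))


class TestLatentInvariantMeasure:
    def test_matches_full_space_power_iteration(self):
        rng = np.random.default_rng(44)
        for _ in range(10):
            n = int(rng.integers(5, 101))
            K = int(rng.integers(2, min(10, n) + 1))
            model = _random_model(rng, n, K)
            mu, _ = lm.latent_invariant_measure(model)
            pi = np.full(n, 1.0 / n)
            for _ in range(500_000):
                nxt = model.lam @ (model.gamma @ pi)
                if np.abs(nxt - pi).sum() < 1e-15:
                    pi = nxt
                    break
                pi = nxt
            assert np.abs(pi - mu.vector).sum() < 1e-10

    def test_k1_measure_is_empirical_pdf(self, planted_instance):
        counts = planted_instance["counts"]
        model, _ = lm.fit_dbmr(counts, 1)
        mu, mu_K = lm.latent_invariant_measure(model)
        marginal = np.asarray(counts.matrix.sum(axis=1)).ravel() / counts.total
        assert np.abs(mu.vector - marginal).sum() < 1e-12
        assert mu_K.tolist() == [1.0]


class TestPropagate:
    def test_unit_mass_returns_product_column(self):
        rng = np.random.default_rng(9)
        model = _random_model(rng, 8, 3)
        pi = np.zeros(8)
        pi[5] = 1.0
        out = lm.propagate(model, pi)
        assert np.allclose(out, (model.lam @ model.gamma)[:, 5])

    def test_output_is_probability_vector(self):
        rng = np.random.default_rng(10)
        model = _random_model(rng, 12, 4)
        out = lm.propagate(model, rng.dirichlet(np.ones(12)))
        assert abs(out.sum() - 1.0) < 1e-12
        assert out.min() >= 0

    def test_invariant_measure_is_fixed_point(self):
        model = _random_model(np.random.default_rng(11), 30, 5)
        mu, _ = lm.latent_invariant_measure(model)
        assert np.abs(lm.propagate(model, mu.vector) - mu.vector).sum() < 1e-10

    def test_malformed_pi_rejected(self):
        model = _random_model(np.random.default_rng(12), 5, 2)
        with pytest.raises(ValidationError):
            lm.propagate(model, np.ones(5))


def _two_block_model(eps1, eps2):
    gamma = np.zeros((2, 10))
    gamma[0, :5] = 1.0
    gamma[1, 5:] = 1.0
    lam = np.zeros((10, 2))
    lam[:5, 0] = (1 - eps1) / 5
    lam[5:, 0] = eps1 / 5
    lam[5:, 1] = (1 - eps2) / 5
    lam[:5, 1] = eps2 / 5
    return lm.LatentModel(gamma, lam, hard=True)


class TestSpectrum:
    def test_weakly_coupled_blocks_have_analytic_second_eigenvalue(self):
        for eps1, eps2 in [(0.05, 0.08), (0.01, 0.02), (0.001, 0.004)]:
            comps = lm.spectrum(_two_block_model(eps1, eps2), 2)
            assert comps.eigenvalues[0] == pytest.approx(1.0, abs=1e-12)
            assert np.real(comps.eigenvalues[1]) == pytest.approx(
                1 - eps1 - eps2, abs=1e-12
            )

    def test_second_eigenvalue_approaches_one_as_coupling_vanishes(self):
        lams = [
            np.real(lm.spectrum(_two_block_model(e, e), 2).eigenvalues[1])
            for e in (0.1, 0.01, 0.001)
        ]
        assert lams[0] < lams[1] < lams[2] < 1.0

    def test_lifted_vectors_are_eigenvectors_of_full_product(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            model = _random_model(rng, 40, 6)
            comps = lm.spectrum(model, 3)
            full = model.lam @ model.gamma
            for m in range(3):
                v = comps.vectors[:, m]
                z = comps.eigenvalues[m]
                assert np.abs(full @ v - z * v).max() <= 1e-8

    def test_psi2_sign_structure_separates_blocks(self):
        comps = lm.spectrum(_two_block_model(0.02, 0.03), 2)
        psi2 = np.real(comps.psi2)
        assert (np.sign(psi2[:5]) == np.sign(psi2[0])).all()
        assert (np.sign(psi2[5:]) == -np.sign(psi2[0])).all()

    def test_requesting_more_components_than_k_rejected(self):
        model, _ = lm.fit_dbmr(_block_diagonal_counts(), 1)
        with pytest.raises(ValidationError):
            lm.spectrum(model, 2)

    def test_sign_convention_largest_entry_positive(self):
        comps = lm.spectrum(_two_block_model(0.05, 0.08), 2)
        for m in range(2):
            v = comps.vectors[:, m]
            assert np.real(v[np.argmax(np.abs(v))]) > 0


class TestModelValidation:
    def test_hard_flag_requires_unit_columns(self):
        gamma = np.array([[0.7, 1.0], [0.3, 0.0]])
        lam = np.array([[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ValidationError):
            lm.LatentModel(gamma, lam, hard=True)

    def test_non_stochastic_columns_rejected(self):
        with pytest.raises(ValidationError):
            lm.LatentModel(np.array([[0.5, 0.5], [0.4, 0.5]]), np.eye(2))
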