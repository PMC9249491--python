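"""Prox operators against brute-force oracles, the A-update against a generic
quadratic solver, full ADMM against an independent splitting solver, and the
kernel-residual decision rule against enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from oskseg.classifier import (RepresentationProblem, admm_solve, classify,
                               soft_threshold, stabilise_psd, svt, update_A)
from oskseg.kernels import rbf_gram
from oskseg.phantom import toy_problem

from oracles import davis_yin_solve, lowrank_sparse_objective, scalar_prox_grid


def _kernel_instance(seed, n_classes=3, n_train=2, n_test=8, dim=3, sigma=2.0):
    """Small PSD V / U pair from Gaussian clusters."""
    tp = toy_problem(seed, n_test, n_train, n_classes, dim)
    V = rbf_gram(tp.dictionary, sigma=sigma)
    U = rbf_gram(tp.dictionary, tp.test, sigma=sigma)
    return V, U, tp


class TestSoftThreshold:
    def test_closed_forms(self):
        x = np.array([[0.5, -1.2]])
        assert np.allclose(soft_threshold(x, 0.7), [[0.0, -0.5]])
        y = np.array([[1.0, -2.0], [0.3, 0.0]])
        assert np.array_equal(soft_threshold(y, 0.0), y)

    def test_matches_grid_search_prox(self, rng):
        x = rng.normal(size=(3, 3))
        tau = 0.4
        out = soft_threshold(x, tau)
        for i in range(3):
            for j in range(3):
                assert out[i, j] == pytest.approx(
                    scalar_prox_grid(x[i, j], tau), abs=1e-4
                )

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-3, 3), st.floats(0, 2))
    def test_shrinkage_properties(self, x, tau):
        y = float(soft_threshold(np.array([x]), tau)[0])
        assert abs(y) <= abs(x) + 1e-15
        assert y * x >= 0
        if abs(x) > tau:
            assert y == pytest.approx(x - np.sign(x) * tau, abs=1e-12)
        else:
            assert y == 0.0


class TestSvt:
    def test_tau_zero_identity(self, rng):
        x = rng.normal(size=(4, 6))
        assert np.array_equal(svt(x, 0.0), x)

    def test_diagonal_closed_form(self):
        assert np.allclose(svt(np.diag([3.0, 1.0]), 2.0), np.diag([1.0, 0.0]))

    def test_large_tau_zeroes(self, rng):
        x = rng.normal(size=(3, 5))
        smax = np.linalg.svd(x, compute_uv=False)[0]
        assert np.allclose(svt(x, smax + 1e-9), 0.0)

    def test_singular_vectors_preserved(self, rng):
        x = rng.normal(size=(5, 5))
        u, s, vt = np.linalg.svd(x)
        out = svt(x, 0.3)
        assert np.allclose(out, (u * np.maximum(s - 0.3, 0)) @ vt, atol=1e-10)


class TestUpdateA:
    def test_identity_closed_form(self):
        U = np.arange(12.0).reshape(3, 4)
        Z = np.zeros((3, 4))
        out = update_A(Z, Z, Z, Z, np.eye(3), U, mu=1.0)
        assert np.allclose(out, U / 3.0)

    def test_stationarity_gradient_vanishes(self, rng):
        V, U, _ = _kernel_instance(0, n_test=7)
        t, n = U.shape
        E, F, Y1, Y2 = (rng.normal(size=(t, n)) for _ in range(4))
        mu = 0.7
        A = update_A(E, F, Y1, Y2, V, U, mu)
        grad = V @ A - U + Y1 + Y2 + mu * (A - E) + mu * (A - F)
        assert np.max(np.abs(grad)) < 1e-8

    def test_matches_generic_quadratic_solver(self, rng):
        V, U, _ = _kernel_instance(1, n_train=1, n_classes=5, n_test=7)
        t, n = U.shape
        assert (t, n) == (5, 7)
        E, F, Y1, Y2 = (rng.normal(size=(t, n)) for _ in range(4))
        mu = 0.5

        def obj(a_flat):
            A = a_flat.reshape(t, n)
            return (0.5 * np.sum(A * (V @ A)) - np.sum(A * U)
                    + np.sum(Y1 * (A - E)) + np.sum(Y2 * (A - F))
                    + mu / 2 * (np.sum((A - E) ** 2) + np.sum((A - F) ** 2)))

        res = minimize(obj, np.zeros(t * n), method="L-BFGS-B",
                       options={"ftol": 1e-15, "gtol": 1e-12})
        ours = update_A(E, F, Y1, Y2, V, U, mu)
        assert np.allclose(ours, res.x.reshape(t, n), atol=1e-5)

    def test_invalid_mu(self):
        z = np.zeros((2, 2))
        with pytest.raises(ValueError):
            update_A(z, z, z, z, np.eye(2), z, mu=0.0)


class TestAdmm:
    def test_unregularised_matches_direct_solve(self):
        V, U, _ = _kernel_instance(2)
        V = V + 0.1 * np.eye(V.shape[0])  # strictly PD
        # fixed penalty: geometric mu growth would truncate the linear
        # convergence of this prox-free special case
        prob = RepresentationProblem(V=V, U=U, lambda_lr=0.0, alpha_sp=0.0,
                                     mu0=0.1, rho=1.0, tol=1e-9, max_iter=500)
        res = admm_solve(prob)
        assert res.converged
        assert np.max(np.abs(res.A - np.linalg.solve(V, U))) < 1e-6

    def test_zero_data_gives_zero(self):
        V = np.eye(4)
        prob = RepresentationProblem(V=V, U=np.zeros((4, 6)))
        res = admm_solve(prob)
        assert np.max(np.abs(res.A)) < 1e-8

    def test_objective_within_tolerance_of_independent_solver(self):
        """T=6, N=8 instance at the shipped penalties: ADMM optimum matches a
        Davis–Yin splitting solver run to high precision."""
        V, U, _ = _kernel_instance(3, n_train=2, n_classes=3, n_test=8)
        prob = RepresentationProblem(V=V, U=U, lambda_lr=0.005, alpha_sp=0.002)
        res = admm_solve(prob)
        a_dy = davis_yin_solve(V, U, 0.005, 0.002, n_iter=20000)
        f_admm = lowrank_sparse_objective(res.A, V, U, 0.005, 0.002)
        f_dy = lowrank_sparse_objective(a_dy, V, U, 0.005, 0.002)
        assert abs(f_admm - f_dy) < 1e-4

    def test_split_residuals_driven_below_tol(self):
        V, U, _ = _kernel_instance(4)
        prob = RepresentationProblem(V=V, U=U)
        res = admm_solve(prob)
        assert res.converged
        assert res.final_residual < prob.tol

    def test_augmented_lagrangian_decreases_at_fixed_mu(self):
        """With rho=1 the full sweep is block-coordinate descent on the
        augmented Lagrangian between multiplier updates: the objective
        history must be non-increasing after the first sweeps."""
        V, U, _ = _kernel_instance(5)
        prob = RepresentationProblem(V=V, U=U, rho=1.0, mu0=1.0, max_iter=60)
        res = admm_solve(prob)
        obj = res.history["objective"].to_numpy()
        assert np.all(np.diff(obj[5:]) <= 1e-8)

    def test_lowrank_and_sparsity_monotone_response(self):
        V, U, _ = _kernel_instance(6, n_test=10)

        def rank_of(lam):
            prob = RepresentationProblem(V=V, U=U, lambda_lr=lam, alpha_sp=0.0)
            s = np.linalg.svd(admm_solve(prob).A, compute_uv=False)
            return int(np.sum(s > 1e-6 * s[0])) if s[0] > 0 else 0

        def nnz_of(alpha):
            prob = RepresentationProblem(V=V, U=U, lambda_lr=0.0,
                                         alpha_sp=alpha)
            A = admm_solve(prob).A
            # threshold above solver noise (split residual scale)
            return int(np.sum(np.abs(A) > 1e-6))

        ranks = [rank_of(l) for l in (0.0, 0.05, 0.5, 2.0)]
        assert all(a >= b for a, b in zip(ranks, ranks[1:]))
        nnzs = [nnz_of(a) for a in (0.0, 0.05, 0.5, 2.0)]
        assert all(a >= b for a, b in zip(nnzs, nnzs[1:]))

    def test_nonconvergence_flagged(self):
        V, U, _ = _kernel_instance(7)
        prob = RepresentationProblem(V=V, U=U, max_iter=3)
        res = admm_solve(prob)
        assert not res.converged
        assert res.n_iter == 3


class TestStabilisePsd:
    def test_psd_input_untouched(self):
        V = rbf_gram(np.random.default_rng(0).normal(size=(5, 2)), sigma=1.0)
        assert np.allclose(stabilise_psd(V), (V + V.T) / 2, atol=1e-12)

    def test_indefinite_clipped(self):
        V = np.diag([1.0, -0.5])
        out = stabilise_psd(V)
        assert np.linalg.eigvalsh(out)[0] >= -1e-12


class TestClassify:
    def test_single_class(self):
        A = np.random.default_rng(0).normal(size=(4, 5))
        V = np.eye(4)
        U = np.zeros((4, 5))
        pred = classify(A, V, U, np.array([2, 2, 2, 2]))
        assert np.all(pred == 2)

    def test_single_class_support_wins(self):
        # column supported on class 1 atoms only, with negative score
        V = np.eye(3)
        U = np.array([[1.0], [0.0], [0.0]])
        A = np.array([[1.0], [0.0], [0.0]])
        labels = np.array([1, 2, 3])
        # class 1 score: 1 - 2 = -1; classes 2,3 score 0 (empty support)
        assert classify(A, V, U, labels)[0] == 1

    def test_matches_brute_force_enumeration(self, rng):
        t, n, C = 8, 12, 4
        labels = rng.integers(1, C + 1, size=t)
        labels[:C] = np.arange(1, C + 1)  # every class represented
        A = rng.normal(size=(t, n))
        M = rng.normal(size=(t, t))
        V = M @ M.T
        U = rng.normal(size=(t, n))
        pred = classify(A, V, U, labels)
        for i in range(n):
            best, best_score = None, np.inf
            for c in range(1, C + 1):
                d = np.where(labels == c, A[:, i], 0.0)
                score = d @ V @ d - 2 * d @ U[:, i]
                if score < best_score - 1e-15:
                    best, best_score = c, score
            assert pred[i] == best

    def test_tie_goes_to_smallest_class(self):
        V = np.eye(2)
        U = np.zeros((2, 1))
        A = np.zeros((2, 1))  # all scores 0 → tie
        assert classify(A, V, U, np.array([3, 1]))[0] == 1
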