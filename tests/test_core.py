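"""EM engine unit tests: equation-level oracles, loop behavior, invariants."""

import numpy as np
import pytest

from structcpd.core import (
    RegistrationConfig,
    estep,
    gaussian_kernel,
    initialize,
    objective_q,
    observed_nll,
    register,
    solve_coefficients,
    transform,
    update_omega,
    update_sigma2,
)
from structcpd.shape_context import CostMatrix, uniform_cost_matrix

from oracles import (
    estep_scalar,
    objective_scalar,
    omega_scalar,
    reference_cpd_trace,
    sigma2_scalar,
    transform_scalar,
)


def _random_instance(seed, nmax=8):
    rng = np.random.default_rng(seed)
    n, m = rng.integers(2, nmax + 1), rng.integers(2, nmax + 1)
    X = rng.normal(size=(n, 2))
    TY = rng.normal(size=(m, 2))
    C = CostMatrix(values=rng.uniform(0.05, 1.0, size=(n, m)), gamma=0.1)
    return rng, X, TY, C


class TestInitialize:
    def test_pooled_variance_single_pair(self):
        st = initialize(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]), RegistrationConfig())
        assert st.sigma2 == pytest.approx(12.5)

    def test_degenerate_identical_points_clamped_to_floor(self):
        cfg = RegistrationConfig(sigma2_floor=1e-8)
        st = initialize(np.zeros((1, 2)), np.zeros((1, 2)), cfg)
        assert st.sigma2 == 1e-8

    def test_zero_coefficients_give_identity_transform(self):
        Y = np.random.default_rng(0).normal(size=(6, 2))
        st = initialize(Y.copy(), Y, RegistrationConfig())
        np.testing.assert_array_equal(transform(Y, st.G, st.W), Y)
        assert np.allclose(np.diag(st.G), 1.0) and np.allclose(st.G, st.G.T)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            initialize(np.zeros((3, 2)), np.zeros((3, 3)), RegistrationConfig())


class TestEStep:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scalar_oracle(self, seed):
        rng, X, TY, C = _random_instance(seed)
        sigma2 = rng.uniform(0.1, 2.0)
        omega = rng.uniform(0.0, 0.9)
        P, Pout = estep(X, TY, C, sigma2, omega)
        Pe, Pe_out = estep_scalar(X, TY, C.values, C.row_sums, sigma2, omega)
        np.testing.assert_allclose(P, Pe, rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(Pout, Pe_out, rtol=0, atol=1e-12)

    def test_posterior_rows_sum_to_one(self):
        _, X, TY, C = _random_instance(3)
        P, Pout = estep(X, TY, C, 0.7, 0.4)
        np.testing.assert_allclose(P.sum(axis=0) + Pout, 1.0, atol=1e-12)

    def test_uniform_costs_reduce_to_plain_cpd(self):
        # with C = 1 the outlier term is omega*M*(2 pi s2)^{D/2}/((1-omega)N)
        rng = np.random.default_rng(4)
        X, TY = rng.normal(size=(5, 2)), rng.normal(size=(3, 2))
        P, _ = estep(X, TY, uniform_cost_matrix(5, 3), 0.5, 0.3)
        sq = ((X[:, None, :] - TY[None, :, :]) ** 2).sum(-1)
        num = np.exp(-sq / 1.0)
        denom = num.sum(1) + 0.3 * 3 * (2 * np.pi * 0.5) / (0.7 * 5)
        np.testing.assert_allclose(P, (num / denom[:, None]).T, rtol=1e-12)

    def test_single_component_no_outliers(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(4, 2))
        TY = rng.normal(size=(1, 2))
        P, Pout = estep(X, TY, uniform_cost_matrix(4, 1), 1.0, 0.0)
        np.testing.assert_allclose(P, 1.0, atol=1e-12)
        np.testing.assert_allclose(Pout, 0.0, atol=1e-12)

    def test_omega_one_rejected(self):
        _, X, TY, C = _random_instance(6)
        with pytest.raises(ValueError):
            estep(X, TY, C, 0.5, 1.0)


class TestMStep:
    @pytest.mark.parametrize("seed", range(10))
    def test_sigma2_matches_scalar_oracle(self, seed):
        rng, X, TY, _ = _random_instance(seed)
        P = rng.uniform(0.0, 1.0, size=(TY.shape[0], X.shape[0]))
        assert update_sigma2(P, X, TY, floor=0.0) == pytest.approx(
            sigma2_scalar(P, X, TY), rel=1e-12
        )

    def test_sigma2_perfect_fit_returns_floor(self):
        X = np.random.default_rng(0).normal(size=(4, 2))
        assert update_sigma2(np.eye(4), X, X, floor=1e-8) == 1e-8

    def test_sigma2_single_pair_arithmetic(self):
        assert update_sigma2(
            np.array([[1.0]]), np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]), floor=0.0
        ) == pytest.approx(12.5)

    def test_sigma2_degenerate_posterior_rejected(self):
        with pytest.raises(ValueError, match="outlier"):
            update_sigma2(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)))

    def test_omega_first_iteration_adopts_new_estimate(self):
        P = np.full((2, 4), 0.1)  # NP = 0.8, omega_new = 0.8
        assert update_omega(P, 0.123, t=1, n_scene=4) == pytest.approx(0.8)

    def test_omega_full_assignment_clamps_at_epsilon(self):
        P = np.eye(3)  # NP = N -> omega_new = 0
        assert update_omega(P, 0.5, t=1, n_scene=3) == pytest.approx(1e-6)

    def test_omega_damped_update(self):
        # NP = 3 over N = 10 -> omega_new = 0.7; t = 2 -> 0.5 + (0.7-0.5)/2
        P = np.full((2, 10), 0.15)
        assert update_omega(P, 0.5, t=2, n_scene=10) == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", range(10))
    def test_omega_matches_scalar_oracle(self, seed):
        rng, X, TY, _ = _random_instance(seed)
        P = rng.uniform(0, 1.0 / TY.shape[0], size=(TY.shape[0], X.shape[0]))
        t = int(rng.integers(1, 10))
        assert update_omega(P, 0.4, t, X.shape[0]) == pytest.approx(
            np.clip(omega_scalar(P, 0.4, t, X.shape[0]), 1e-6, 1 - 1e-6), rel=1e-12
        )


class TestKernelSolve:
    def test_identity_pairing_fixed_point(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        G = gaussian_kernel(X, 2.0)
        W = solve_coefficients(G, np.eye(5), X, X, lambda_=2.0, sigma2=0.5)
        np.testing.assert_allclose(W, 0.0, atol=1e-12)
        np.testing.assert_allclose(transform(X, G, W), X, atol=1e-12)

    def test_zero_regularization_moves_centroids_to_weighted_means(self):
        rng = np.random.default_rng(1)
        X, Y = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
        P = rng.uniform(0.1, 1.0, size=(4, 4))
        G = gaussian_kernel(Y, 2.0)
        W = solve_coefficients(G, P, X, Y, lambda_=0.0, sigma2=0.5)
        target = (P @ X) / P.sum(axis=1)[:, None]
        np.testing.assert_allclose(transform(Y, G, W), target, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_solution_satisfies_linear_system(self, seed):
        rng = np.random.default_rng(seed)
        X, Y = rng.normal(size=(6, 2)), rng.normal(size=(5, 2))
        P = rng.uniform(0.0, 1.0, size=(5, 6))
        G = gaussian_kernel(Y, 2.0)
        sigma2, lam = rng.uniform(0.05, 1.0), rng.uniform(0.5, 4.0)
        W = solve_coefficients(G, P, X, Y, lam, sigma2)
        p1 = P.sum(axis=1)
        A = G + lam * sigma2 * np.diag(1.0 / p1)
        rhs = (P @ X) / p1[:, None] - Y
        assert np.linalg.norm(A @ W - rhs) <= 1e-8 * np.linalg.norm(rhs)

    @pytest.mark.parametrize("seed", range(5))
    def test_transform_matches_per_point_loop(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.normal(size=(6, 2))
        G = gaussian_kernel(Y, 1.5)
        W = rng.normal(size=(6, 2))
        np.testing.assert_allclose(transform(Y, G, W), transform_scalar(Y, G, W), rtol=1e-12)

    def test_unit_kernel_single_point(self):
        Y = np.array([[0.0, 0.0]])
        np.testing.assert_array_equal(
            transform(Y, np.array([[1.0]]), np.array([[2.0, 3.0]])), [[2.0, 3.0]]
        )


class TestObjective:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scalar_oracle(self, seed):
        rng, X, TY, _ = _random_instance(seed)
        m = TY.shape[0]
        P = rng.uniform(0, 1.0 / m, size=(m, X.shape[0]))
        W = rng.normal(size=(m, 2))
        G = gaussian_kernel(TY, 2.0)
        got = objective_q(P, X, TY, W, G, sigma2=0.3, omega=0.25, lambda_=2.0)
        want = objective_scalar(P, X, TY, W, G, 0.3, 0.25, 2.0)
        assert got == pytest.approx(want, rel=1e-12)

    def test_zero_displacement_closed_form(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0]])
        P = np.eye(2)
        W = np.zeros((2, 2))
        G = gaussian_kernel(X, 2.0)
        got = objective_q(P, X, X, W, G, sigma2=1e-8, omega=0.5, lambda_=2.0)
        want = 2.0 * np.log(1e-8) - 2.0 * np.log(0.5)
        assert got == pytest.approx(want, rel=1e-12)


class TestRegister:
    def test_identity_registration(self):
        Y = np.random.default_rng(0).normal(size=(40, 2))
        res = register(Y.copy(), Y, RegistrationConfig())
        rmse = np.sqrt(((res.transformed_model - Y) ** 2).sum(1).mean())
        assert rmse < 1e-6

    def test_baseline_cpd_equivalence_small(self):
        rng = np.random.default_rng(11)
        Y = rng.normal(size=(12, 2))
        X = Y + rng.normal(0, 0.1, size=Y.shape)
        cfg = RegistrationConfig(
            omega0=0.2, use_structure=False, auto_omega=False,
            normalize=False, max_iter=25, tol=1e-300, keep_states=True,
        )
        res = register(X, Y, cfg)
        ref = reference_cpd_trace(X, Y, omega=0.2, lam=2.0, beta=2.0, max_iter=25)
        for t, (P_ref, s2_ref, W_ref) in enumerate(ref):
            np.testing.assert_allclose(res.P_states[t], P_ref, atol=1e-8)
            assert res.sigma2_trace[t] == pytest.approx(s2_ref, abs=1e-8)
            np.testing.assert_allclose(res.W_states[t], W_ref, atol=1e-8)

    def test_observed_nll_monotone_with_frozen_omega(self):
        for seed in range(4):
            rng = np.random.default_rng(seed)
            X, Y = rng.normal(size=(20, 2)), rng.normal(size=(15, 2))
            res = register(X, Y, RegistrationConfig(use_structure=False, auto_omega=False, omega0=0.2))
            assert (np.diff(res.nll_trace) <= 1e-9).all()

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 2))
        Y = X + rng.normal(0, 0.05, size=X.shape)
        shift = np.array([12.0, -7.0])
        base = register(X, Y, RegistrationConfig())
        moved = register(X + shift, Y + shift, RegistrationConfig())
        np.testing.assert_allclose(moved.transformed_model, base.transformed_model + shift, atol=1e-6)

    def test_posterior_normalization_every_iteration(self):
        rng = np.random.default_rng(3)
        X, Y = rng.normal(size=(15, 2)), rng.normal(size=(12, 2))
        res = register(X, Y, RegistrationConfig(max_iter=20, keep_states=True))
        for P in res.P_states:
            total = P.sum(axis=0)
            assert (total <= 1 + 1e-12).all()

    def test_frozen_omega_stays_at_initial_value(self):
        rng = np.random.default_rng(4)
        X, Y = rng.normal(size=(15, 2)), rng.normal(size=(15, 2))
        res = register(X, Y, RegistrationConfig(omega0=0.35, auto_omega=False, max_iter=10))
        assert np.allclose(res.omega_trace, 0.35)

    def test_structure_flag_warns_and_falls_back_in_3d(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        Y = X + 0.01 * rng.normal(size=(10, 3))
        with pytest.warns(UserWarning, match="2-D"):
            res = register(X, Y, RegistrationConfig(max_iter=5))
        assert res.transformed_model.shape == (10, 3)

    def test_traces_have_run_length(self):
        rng = np.random.default_rng(6)
        X, Y = rng.normal(size=(10, 2)), rng.normal(size=(10, 2))
        res = register(X, Y, RegistrationConfig(max_iter=7, tol=1e-300))
        assert res.n_iter == 7
        assert len(res.omega_trace) == len(res.sigma2_trace) == len(res.Q_trace) == 7

    def test_warp_recovery_regression_bound(self):
        from structcpd.synthetic import DegradationSpec, make_benchmark_case
        from structcpd.evaluation import rmse_points

        case = make_benchmark_case(
            DegradationSpec(kind="deformation", level=0.03, seed=7, template="fishlike", n_points=60)
        )
        res = register(case.scene, case.model, RegistrationConfig())
        assert rmse_points(res.transformed_model, case.truth_pairs, case.scene) < 0.05
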