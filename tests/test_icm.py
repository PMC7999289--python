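"""Closed-form conditional-mode updates and the ICM sweep loop."""
import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import acsicm as m
from acsicm.icm import _update_alphas
from util import make_synthetic, random_instance


class TestIgConditionalMode:
    def test_prior_mode_with_no_data(self):
        assert m.ig_conditional_mode(2.0, 1.0, 0, 0.0) == pytest.approx(1.0 / 3.0)

    def test_arithmetic_example(self):
        assert m.ig_conditional_mode(2.0, 1.0, 1, 2.0) == pytest.approx(3.0 / 3.5)

    def test_matches_golden_section_slice_of_objective(self):
        """The sensor-noise update maximizes the 1-D slice of the objective."""
        dataset, state, sources, grid, hyper = random_instance(11)
        eps_M = dataset.M - dataset.X_M @ sources.S
        half_ssq = 0.5 * float(np.sum(eps_M * dataset.solve_HM(eps_M)))
        mode = m.ig_conditional_mode(hyper.a_M, hyper.b_M, dataset.T * dataset.n_M, half_ssq)

        def neg(log_s2):
            st2 = state.copy()
            st2.sigma2_M = float(np.exp(log_s2))
            return -m.log_joint(dataset, st2, sources, grid, hyper)

        res = minimize_scalar(neg, bracket=(-5, 0, 5), method="golden",
                              options={"xtol": 1e-10})
        assert mode == pytest.approx(float(np.exp(res.x)), rel=1e-6)

    def test_invalid_prior_rejected(self):
        with pytest.raises(m.InputError):
            m.ig_conditional_mode(0.0, 1.0, 1, 1.0)


class TestArMatrixUpdate:
    def test_zero_means_give_zero_matrix(self):
        np.testing.assert_array_equal(
            m.update_ar_matrix(np.zeros((2, 5)), 1.0, 1.0), np.zeros((2, 2))
        )

    def test_scalar_ridge_example(self):
        """K=2 with mu_A = (1, 2, 4): A = (1*2 + 2*4)/(1 + 1 + 4) = 10/6."""
        A = m.update_ar_matrix(np.array([[1.0, 2.0, 4.0]]), 1.0, 1.0)
        assert A[0, 0] == pytest.approx(10.0 / 6.0)

    def test_matches_numeric_block_maximization(self):
        dataset, state, sources, grid, hyper = random_instance(12, K=3, T=6)
        closed = m.update_ar_matrix(state.mu_A, state.sigma2_a, hyper.sigma2_A)

        from scipy.optimize import minimize

        def neg(vecA):
            st2 = state.copy()
            st2.A = vecA.reshape(2, 2)
            return -m.log_joint(dataset, st2, sources, grid, hyper)

        res = minimize(neg, np.zeros(4), method="BFGS", options={"gtol": 1e-10})
        np.testing.assert_allclose(closed.ravel(), res.x, rtol=1e-5, atol=1e-7)


class TestComponentMeanUpdate:
    def test_no_assignments_and_zero_ar_drive_means_to_zero(self):
        dataset, state, sources, grid, hyper = random_instance(13)
        state.A = np.zeros_like(state.A)
        state.Z = np.zeros_like(state.Z)
        state.Z[:, 0] = 1  # everything inactive
        mu = m.update_component_means(sources, state, grid, hyper)
        np.testing.assert_allclose(mu, 0.0, atol=1e-12)

    def test_final_time_block_gradient_vanishes(self):
        """After the time-ordered pass the last block is an exact conditional mode."""
        dataset, state, sources, grid, hyper = random_instance(14)
        state.mu = m.update_component_means(sources, state, grid, hyper)
        T = dataset.T
        base = m.log_joint(dataset, state, sources, grid, hyper)
        for k in range(1, state.K):
            for h in (1e-5, -1e-5):
                st2 = state.copy()
                st2.mu[k, T - 1] += h
                assert m.log_joint(dataset, st2, sources, grid, hyper) <= base + 1e-9


class TestSourceUpdate:
    def test_identity_leadfields_average_the_modalities(self):
        """With X = I, H = I, unit noise and a flat mixture the mode is the
        plain average of the two modality readings."""
        rng = np.random.default_rng(15)
        P = T = 3
        coords = rng.uniform(0, 1, (P, 3))
        grid = m.build_grid(coords, (2, 2, 2))
        dataset = m.SensorDataset(M=rng.standard_normal((P, T)),
                                  E=rng.standard_normal((P, T)),
                                  X_M=np.eye(P), X_E=np.eye(P), coords=coords)
        Z = np.zeros((grid.N_v, 2), dtype=np.int8)
        Z[:, 1] = 1
        state = m.MixtureState(Z=Z, mu=np.zeros((2, T)), alpha=np.array([1e12, 1e12]),
                               A=np.zeros((1, 1)), sigma2_a=1, sigma2_E=1, sigma2_M=1)
        out = m.update_sources(dataset, state, m.SourceField(np.zeros((P, T))), grid=grid)
        np.testing.assert_allclose(out.S, (dataset.M + dataset.E) / 2.0, rtol=1e-9)

    def test_noiseless_data_with_matching_prior_is_a_fixed_point(self):
        rng = np.random.default_rng(16)
        P, T = 4, 5
        coords = rng.uniform(0, 1, (P, 3))
        grid = m.build_grid(coords, (1, 1, 1))
        course = np.sin(np.linspace(0, 2, T))
        S_star = np.tile(course, (P, 1))
        X_M, X_E = m.make_lead_fields(6, 6, P, seed=0)
        dataset = m.SensorDataset(M=X_M @ S_star, E=X_E @ S_star,
                                  X_M=X_M, X_E=X_E, coords=coords)
        Z = np.array([[0, 1]], dtype=np.int8)
        mu = np.vstack([np.zeros(T), course])
        state = m.MixtureState(Z=Z, mu=mu, alpha=np.array([1.0, 1e-6]),
                               A=np.zeros((1, 1)), sigma2_a=1, sigma2_E=1, sigma2_M=1)
        out = m.update_sources(dataset, state, m.SourceField(S_star.copy()), grid=grid)
        np.testing.assert_allclose(out.S, S_star, atol=1e-8)


class TestLabelUpdate:
    def test_nearest_mean_wins_without_spatial_term(self):
        rng = np.random.default_rng(17)
        T = 4
        coords = np.array([[0.5, 0.5, 0.5]])
        grid = m.build_grid(coords, (1, 1, 1))
        mu = np.vstack([np.zeros(T), np.full(T, 3.0)])
        S = np.full((1, T), 2.9)  # much closer to component 2
        state = m.MixtureState(Z=np.array([[1, 0]], dtype=np.int8), mu=mu,
                               alpha=np.ones(2), A=np.zeros((1, 1)),
                               sigma2_a=1, sigma2_E=1, sigma2_M=1)
        hyper = m.Hyperparameters(K=2, beta=0.0)
        Z = m.update_labels_chequerboard(m.SourceField(S), state, grid, hyper)
        assert Z[0, 1] == 1

    def test_huge_beta_forces_neighbour_consensus(self):
        dataset, state, sources, grid, hyper = random_instance(18)
        hyper = m.Hyperparameters(K=state.K, beta=1e3)
        state.Z[:] = 0
        state.Z[:, 2] = 1  # all neighbours agree on component 3
        Z = m.update_labels_chequerboard(sources, state, grid, hyper, colours=("black",))
        black = np.flatnonzero(grid.parity == 0)
        assert np.all(Z[black, 2] == 1)

    def test_matches_per_voxel_enumeration(self):
        dataset, state, sources, grid, hyper = random_instance(19)
        Z_new = m.update_labels_chequerboard(sources, state, grid, hyper, colours=("black",))
        black = np.flatnonzero(grid.parity == 0)
        for v in black:
            scores = []
            for h in range(state.K):
                st2 = state.copy()
                st2.Z[v] = 0
                st2.Z[v, h] = 1
                scores.append(m.log_joint(dataset, st2, sources, grid, hyper))
            assert np.argmax(Z_new[v]) == int(np.argmax(scores))


class TestIcmRun:
    def test_deterministic(self):
        dataset, truth, grid = make_synthetic(0, P=30, n=10, T=10, dims=(2, 2, 2))
        hyper = m.Hyperparameters(K=3)
        init = m.default_init(dataset, grid, hyper, seed=1)
        f1 = m.icm_run(dataset, init, hyper, grid)
        f2 = m.icm_run(dataset, init, hyper, grid)
        np.testing.assert_array_equal(f1.sources.S, f2.sources.S)
        np.testing.assert_array_equal(f1.state.Z, f2.state.Z)
        assert f1.objective_trace == f2.objective_trace

    def test_restart_from_fixed_point_converges_in_one_sweep(self):
        dataset, truth, grid = make_synthetic(1, P=30, n=10, T=10, dims=(2, 2, 2))
        hyper = m.Hyperparameters(K=3)
        init = m.default_init(dataset, grid, hyper, seed=1)
        # drive the first run to an essentially exact fixed point
        fit = m.icm_run(dataset, init, hyper, grid,
                        settings=m.IcmSettings(tol=1e-12, max_sweeps=500))
        refit = m.icm_run(dataset, (fit.state, fit.sources), hyper, grid)
        assert refit.converged and refit.iterations == 1
        assert refit.objective_trace[0] == pytest.approx(fit.objective_trace[-1], abs=1e-6)

    def test_objective_trace_monotone_on_synthetic_data(self):
        for seed in (2, 3):
            dataset, truth, grid = make_synthetic(seed, P=30, n=10, T=10, dims=(2, 2, 2))
            hyper = m.Hyperparameters(K=3)
            init = m.default_init(dataset, grid, hyper, seed=1)
            fit = m.icm_run(dataset, init, hyper, grid)
            assert np.all(np.diff(fit.objective_trace) >= -1e-8)

    def test_alpha_update_keeps_components_positive(self):
        dataset, state, sources, grid, hyper = random_instance(20)
        sources.S[:] = state.mu[state.labels[grid.v]]  # perfect fit everywhere
        alpha = _update_alphas(sources, state, grid, hyper, jitter=1e-10)
        assert np.all(alpha > 0)

    def test_settings_validation(self):
        with pytest.raises(m.InputError):
            m.IcmSettings(tol=0.0)
        with pytest.raises(m.InputError):
            m.IcmSettings(max_sweeps=0)
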