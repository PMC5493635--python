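import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blinkcomp import (EmitterSet, PixelGrid, PSFModel, build_system_matrix,
                       coefficients, component_set, compute_components,
                       empirical_J, o_matrix, reconstruct_J, simulate_stack)
from blinkcomp.components import (component_report, eq_identity_residual,
                                  numerical_rank)
from conftest import random_system


class TestOMatrix:
    def test_zero_mu_is_scaled_identity(self):
        O = o_matrix(4, 0.0, 2.0)
        np.testing.assert_array_equal(O.matrix, 4.0 * np.eye(4))

    def test_closed_form_eigenvalues_small_case(self):
        O = o_matrix(3, 1.0, 2.0)
        np.testing.assert_allclose(sorted(O.eigenvalues()), [4.0, 4.0, 7.0])

    @given(mu=st.floats(0.1, 50), sigma=st.floats(0.1, 50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_closed_form_matches_eigensolver(self, mu, sigma):
        O = o_matrix(5, mu, sigma)
        w = np.linalg.eigvalsh(O.matrix)
        assert np.abs(np.sort(w) - np.sort(O.eigenvalues())).max() < 1e-8

    def test_leading_eigenvector_is_all_ones(self):
        O = o_matrix(6, 2.0, 1.0)
        v = O.leading_eigenvector()
        np.testing.assert_allclose(O.matrix @ v, O.eigenvalues()[0] * v)

    def test_invalid_M_rejected(self):
        with pytest.raises(ValueError):
            o_matrix(0, 1.0, 1.0)


class TestComponents:
    @given(seed=st.integers(0, 2 ** 16), M=st.integers(2, 6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_identity_MC1_eq_C2_plus_C3(self, seed, M):
        G = random_system(np.random.default_rng(seed), N=8, M=M)
        C1, C2, C3 = compute_components(G)
        assert eq_identity_residual(C1, C2, C3, M) < 1e-12

    def test_coincident_emitters_collapse(self):
        g = np.array([0.2, 1.0, 0.4])
        G = np.stack([g, g], axis=1)
        C1, C2, C3 = compute_components(G)
        np.testing.assert_allclose(C1, C2, atol=1e-15)
        np.testing.assert_allclose(C2, C3, atol=1e-15)

    def test_well_separated_pair_magnitudes(self, psf):
        # peak-normalised emitter images beyond the Rayleigh limit
        grid = PixelGrid.sliding(700.0, 100.0, 2.0)
        sm = build_system_matrix(EmitterSet.uniform(2, 400.0), grid, psf,
                                 normalize_columns=True)
        C1, C2, C3 = compute_components(sm)
        assert C1.max() == pytest.approx(0.25, abs=0.01)
        assert C2.max() == pytest.approx(0.50, abs=0.01)

    def test_single_emitter_has_no_C3(self):
        C1, C2, C3 = compute_components(np.ones((4, 1)))
        assert C3 is None
        np.testing.assert_allclose(C1, C2)

    def test_C1_rank_one_with_mean_image_eigenvector(self, pair_100nm):
        C1, _, _ = compute_components(pair_100nm)
        assert numerical_rank(C1) == 1
        w, U = np.linalg.eigh(C1)
        gt = pair_100nm.mean_image
        cos = abs(U[:, -1] @ gt) / np.linalg.norm(gt)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_leading_eigenvectors_align_with_mean_image(self, pair_100nm):
        _, C2, C3 = compute_components(pair_100nm)
        gt = pair_100nm.mean_image / np.linalg.norm(pair_100nm.mean_image)
        for C in (C2, C3):
            w, U = np.linalg.eigh(C)
            lead = U[:, np.argmax(np.abs(w))]
            assert abs(lead @ gt) > 0.99

    def test_rank_of_C2_counts_distinct_positions(self, psf, camera10):
        for n_emit in (2, 3, 4):
            sm = build_system_matrix(
                EmitterSet.uniform(n_emit, 100.0), PixelGrid.camera(12, 100.0),
                psf)
            _, C2, _ = compute_components(sm)
            assert numerical_rank(C2) == n_emit

    def test_component_combinations(self, psf, ideal_grid):
        # b/a = M-1 reproduces rank-1 C1; b/a = -1 suppresses the mean image
        sm = build_system_matrix(EmitterSet.uniform(2, 100.0), ideal_grid, psf)
        C1, C2, C3 = compute_components(sm)
        M = 2
        np.testing.assert_allclose(C2 + (M - 1) * C3, M * C1, atol=1e-12)
        diff = C2 - C3
        w, U = np.linalg.eigh(diff)
        lead = U[:, np.argmax(np.abs(w))]
        gt = sm.mean_image / np.linalg.norm(sm.mean_image)
        assert abs(lead @ gt) < 0.5


class TestCoefficients:
    def test_single_emitter_no_cross_content(self):
        assert coefficients(10, 1, 2.0, 3.0)[1] == 0.0

    def test_hand_arithmetic(self):
        c1, c2 = coefficients(1000, 2, 1.0, 2.0)
        assert (c1, c2) == (12000.0, 4000.0)

    @given(M=st.integers(1, 50), mu=st.floats(0.0, 100),
           sigma=st.floats(0.01, 100))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_c2_always_below_c1(self, M, mu, sigma):
        c1, c2 = coefficients(100, M, mu, sigma)
        assert c1 > 0 and c2 >= 0 and c2 / c1 < 1


class TestReconstruction:
    def test_matches_K_G_O_Gt(self, rng):
        G = random_system(rng, N=6, M=3)
        K, mu, sigma = 500, 3.0, 2.0
        cs = component_set(G, K, mu, sigma)
        J = reconstruct_J(cs)
        oracle = K * G @ o_matrix(3, mu, sigma).matrix @ G.T
        assert np.abs(J - oracle).max() < 1e-9 * np.abs(oracle).max()

    def test_output_symmetric_psd(self, rng):
        cs = component_set(random_system(rng), 100, 1.0, 1.0)
        J = reconstruct_J(cs)
        np.testing.assert_allclose(J, J.T, atol=1e-12)
        assert np.linalg.eigvalsh(J).min() > -1e-9 * np.abs(J).max()

    def test_small_sigma_limit_is_pure_mean_image(self, rng):
        G = random_system(rng, N=5, M=2)
        K, mu = 100, 4.0
        cs = component_set(G, K, mu, 1e-8)
        np.testing.assert_allclose(reconstruct_J(cs),
                                   K * 4 * mu ** 2 * cs.C1, rtol=1e-10)

    def test_report_serializable(self, rng):
        import json
        rep = component_report(component_set(random_system(rng), 10, 1.0, 2.0))
        json.dumps(rep)
        assert rep["c2_over_c1"] < 1
        assert rep["identity_residual"] < 1e-12


class TestEmpiricalJ:
    def test_zero_stack(self):
        np.testing.assert_array_equal(empirical_J(np.zeros((4, 9))),
                                      np.zeros((4, 4)))

    def test_single_frame_rank_one(self, rng):
        I = rng.random((5, 1))
        assert np.linalg.matrix_rank(empirical_J(I)) == 1

    def test_convergence_to_model(self, rng, psf, camera10):
        # i.i.d. per-frame counts (assumptions hold exactly); at K = 1e5
        # the empirical Gram matrix matches the model within 5 %
        sm = build_system_matrix(EmitterSet.uniform(2, 100.0), camera10, psf)
        K = 100_000
        S = np.where(rng.random((2, K)) < 0.4,
                     rng.poisson(300.0, (2, K)), 0).astype(float)
        mu, sigma = S.mean(), np.sqrt(S.var(axis=1, ddof=1).mean())
        J_emp = empirical_J(simulate_stack(sm, S))
        J_mod = reconstruct_J(component_set(sm, K, mu, sigma))
        rel = np.linalg.norm(J_emp - J_mod) / np.linalg.norm(J_mod)
        assert rel < 0.05

    def test_error_decreases_with_K(self, psf, camera10):
        sm = build_system_matrix(EmitterSet.uniform(2, 100.0), camera10, psf)
        errs = []
        for K in (1000, 100_000):
            rng = np.random.default_rng(5)
            S = rng.poisson(100.0, (2, K)).astype(float)
            mu, sigma = S.mean(), np.sqrt(S.var(axis=1, ddof=1).mean())
            J_emp = empirical_J(simulate_stack(sm, S))
            J_mod = reconstruct_J(component_set(sm, K, mu, sigma))
            errs.append(np.linalg.norm(J_emp - J_mod) / np.linalg.norm(J_mod))
        assert errs[1] < errs[0]
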