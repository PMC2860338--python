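"""Solver components: residuals, step sizes, schemes, convergence metrics."""

import numpy as np
import pytest
from scipy import sparse

from sparsart import (
    DivergenceError,
    HaarTransform,
    ShrinkageParams,
    SolverConfig,
    estimate_alpha,
    forward_project,
    generate_phantom,
    interior_radius,
    ista_step,
    rre,
    run_scheme,
    sart_residual,
    sart_step,
    step_size_beta,
)
from sparsart.geometry import SystemMatrix
from sparsart.shrinkage import lp_radius
from sparsart.solver import ConvergenceLog


def dense_system(rng, M=8, N=16):
    W = rng.uniform(0.0, 1.0, size=(M, N))
    W[rng.uniform(size=(M, N)) < 0.3] = 0.0
    return SystemMatrix.from_matrix(sparse.csr_matrix(W))


class TestRRE:
    def test_basic_values(self, rng):
        f_star = rng.normal(size=25)
        assert rre(f_star, f_star) == 0.0
        assert rre(np.zeros(25), f_star) == pytest.approx(100.0)
        assert rre(1.01 * f_star, f_star) == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            rre(np.ones(4), np.zeros(4))


class TestSartResidual:
    def test_zero_at_consistent_truth(self, rng):
        A = dense_system(rng)
        f = rng.uniform(size=16)
        g = A.weights @ f
        assert np.allclose(sart_residual(A, g, f), 0.0, atol=1e-12)

    def test_matches_dense_oracle_from_zero(self, rng):
        A = dense_system(rng)
        g = rng.uniform(size=8)
        W = A.weights.toarray()
        lam_m = np.diag(A.lam_row)
        lam_n = np.diag(A.lam_col)
        expected = lam_n @ W.T @ lam_m @ g
        assert np.allclose(sart_residual(A, g, np.zeros(16)), expected, atol=1e-12)

    def test_linear_in_residual(self, rng):
        A = dense_system(rng)
        f = rng.uniform(size=16)
        g = A.weights @ f
        r1 = sart_residual(A, g + 1.0, f)
        r2 = sart_residual(A, g + 2.0, f)
        assert np.allclose(r2, 2 * r1, atol=1e-12)


class TestSartStep:
    def test_lambda_zero_is_identity_and_truth_is_fixed_point(self, rng):
        A = dense_system(rng)
        f = rng.uniform(size=16)
        g = A.weights @ f
        f0 = rng.uniform(size=16)
        # the (0, 2) relaxation range excludes 0; check the limit analytically
        assert np.allclose(sart_step(f0, A, g, 1e-12), f0, atol=1e-9)
        assert np.allclose(sart_step(f, A, g, 1.0), f, atol=1e-12)

    def test_error_strictly_decreases_on_well_posed_toy(self):
        img = generate_phantom(16)
        from sparsart import FanBeamGeometry, build_system_matrix

        A = build_system_matrix(FanBeamGeometry(n_views=30, n_detectors=16), 16)
        g = forward_project(A, img)
        f = np.zeros(A.shape[1])
        errors = [rre(f, img)]
        for _ in range(20):
            f = sart_step(f, A, g, 1.0)
            errors.append(rre(f, img))
        assert all(e2 < e1 for e1, e2 in zip(errors, errors[1:]))


class TestAlphaAndBeta:
    def test_identity_matrix_gives_alpha0_and_beta_one(self, rng):
        A = SystemMatrix.from_matrix(sparse.identity(9, format="csr"))
        assert estimate_alpha(A, 2.0) == pytest.approx(2.0)
        assert estimate_alpha(A, 0.7) == pytest.approx(0.7)
        r = rng.normal(size=9)
        assert step_size_beta(A, r) == pytest.approx(1.0)

    def test_alpha_matches_dense_algebra(self, rng):
        A = dense_system(rng, M=6, N=16)
        W = A.weights.toarray()
        lam_m = np.diag(A.lam_row)
        lam_n = np.diag(A.lam_col)
        ones = np.ones(16)
        num = np.max(W.T @ W @ ones)
        den = np.max(lam_n @ W.T @ lam_m @ lam_m @ W @ lam_n @ ones)
        expected = 2.0 * np.sqrt(num / den)
        assert estimate_alpha(A, 2.0) == pytest.approx(expected, rel=1e-12)

    def test_beta_matches_dense_and_scales_inversely(self, rng):
        A = dense_system(rng, M=6, N=16)
        r = rng.normal(size=16)
        W = A.weights.toarray()
        expected = np.dot(r, r) / np.dot(W @ r, W @ r)
        assert step_size_beta(A, r) == pytest.approx(expected, rel=1e-12)
        A2 = SystemMatrix.from_matrix(sparse.csr_matrix(3.0 * W))
        assert step_size_beta(A2, r) == pytest.approx(expected / 9.0, rel=1e-12)

    def test_beta_zero_residual_rejected(self, rng):
        A = dense_system(rng)
        with pytest.raises(ValueError):
            step_size_beta(A, np.zeros(16))


class TestInteriorRadius:
    def test_schedule_endpoints_and_midpoint(self):
        assert interior_radius(20000, 20000, 5.0) == pytest.approx(5.0)
        # (2^-20)^0.05 = 2^-1 exactly
        assert interior_radius(1, 2**20, 1.0) == pytest.approx(0.4 + 0.6 * 0.5)
        assert interior_radius(1, 20000, 1.0) == pytest.approx(
            0.4 + 0.6 * (1 / 20000) ** 0.05
        )
        # frozen direct evaluation of the k=1 factor
        assert interior_radius(1, 20000, 1.0) == pytest.approx(0.7656788, abs=1e-6)


class TestIstaStep:
    def test_reduces_to_landweber_with_zero_weight(self, rng):
        n = 4
        tr = HaarTransform(n)
        W = rng.uniform(0, 0.2, size=(n * n, n * n))
        A = SystemMatrix.from_matrix(sparse.csr_matrix(W))
        f = rng.normal(size=n * n)
        g = rng.normal(size=n * n)
        out = ista_step(f, A, g, tr, ShrinkageParams(p=1.0, w=0.0))
        expected = f + W.T @ (g - W @ f)
        assert np.allclose(out, expected, atol=1e-10)

    def test_truth_is_fixed_point_without_regularization(self, rng):
        n = 4
        tr = HaarTransform(n)
        W = rng.uniform(0, 0.2, size=(20, n * n))
        A = SystemMatrix.from_matrix(sparse.csr_matrix(W))
        f = rng.uniform(size=n * n)
        g = W @ f
        out = ista_step(f, A, g, tr, ShrinkageParams(p=1.5, w=0.0))
        assert np.allclose(out, f, atol=1e-12)

    def test_scalar_recurrence_converges_to_closed_form(self):
        # 1 pixel, 1 measurement, a = 0.5, g = 1:  f <- f + 0.5(1 - 0.5 f)
        # fixed point 2, contraction factor 0.75
        tr = HaarTransform(2)
        W = sparse.csr_matrix(0.5 * np.eye(4))
        A = SystemMatrix.from_matrix(W)
        g = np.ones(4)
        f = np.zeros(4)
        for k in range(1, 60):
            f = ista_step(f, A, g, tr, ShrinkageParams(p=1.0, w=0.0))
            assert np.allclose(f, 2.0 * (1 - 0.75**k), rtol=1e-10)
        assert np.allclose(f, 2.0, atol=1e-6)


class TestRunScheme:
    def test_scheme_b_starting_at_truth_stops_immediately(self, system_small, phantom32):
        g = forward_project(system_small, phantom32)
        cfg = SolverConfig(scheme="B", max_iter=50)
        log = run_scheme(cfg, system_small, g, phantom32, f0=phantom32.ravel())
        assert log.stop_iteration == 1
        assert log.final_rre == pytest.approx(0.0, abs=1e-8)

    def test_scheme_a_beats_scheme_b_on_few_view_data(self, phantom32):
        from sparsart import FanBeamGeometry, build_system_matrix

        A = build_system_matrix(FanBeamGeometry(n_views=10, n_detectors=32), 32)
        g = forward_project(A, phantom32)
        tr = HaarTransform(32)
        log_a = run_scheme(SolverConfig(scheme="A", max_iter=300), A, g, phantom32, tr)
        log_b = run_scheme(SolverConfig(scheme="B", max_iter=300), A, g, phantom32, tr)
        assert log_a.final_rre < log_b.final_rre

    def test_projected_iterates_stay_in_ball(self, system_small, phantom32):
        tr = HaarTransform(32)
        g = forward_project(system_small, phantom32)
        r_star = lp_radius(tr.forward(phantom32).coeffs, 1.0)
        cfg = SolverConfig(scheme="A", max_iter=40, nonneg=False)
        log = run_scheme(cfg, system_small, g, phantom32, tr)
        c = tr.forward(log.final_image)
        assert lp_radius(c.coeffs, 1.0) <= r_star * (1 + 1e-7) + 1e-7

    def test_scheme_c_iterates_respect_radius_schedule(self, system_small, phantom32):
        tr = HaarTransform(32)
        g = forward_project(system_small, phantom32)
        r_star = lp_radius(tr.forward(phantom32).coeffs, 1.0)
        cfg = SolverConfig(scheme="C", max_iter=30, nonneg=False)
        log = run_scheme(cfg, system_small, g, phantom32, tr)
        k_last = log.stop_iteration
        target = interior_radius(k_last, cfg.max_iter, r_star)
        c = tr.forward(log.final_image)
        assert lp_radius(c.coeffs, 1.0) <= target * (1 + 1e-7) + 1e-7

    def test_unweighted_step_equals_classical_sart_cross_check(self, rng):
        # with alpha*beta replaced by a relaxation factor, one projected-free
        # iteration must equal sart_step exactly (shared code path check)
        A = dense_system(rng)
        f = rng.uniform(size=16)
        g = A.weights @ rng.uniform(size=16)
        step = sart_residual(A, g, f)
        assert np.allclose(f + 1.3 * step, sart_step(f, A, g, 1.3), atol=1e-14)

    def test_direct_scheme_uses_unit_weights(self, rng):
        A = dense_system(rng)
        g = rng.uniform(size=8)
        rt_direct = sart_residual(A, g, np.zeros(16), direct=True)
        assert np.allclose(rt_direct, A.weights.T @ g, atol=1e-14)

    def test_divergence_raises_with_guidance(self, phantom32, system_small):
        g = forward_project(system_small, phantom32)
        tr = HaarTransform(32)
        cfg = SolverConfig(scheme="B", alpha0=5000.0, max_iter=400, nonneg=False)
        with pytest.raises(DivergenceError, match="alpha0"):
            run_scheme(cfg, system_small, g, phantom32, tr)

    def test_missing_transform_rejected(self, system_small, phantom32):
        g = forward_project(system_small, phantom32)
        with pytest.raises(ValueError, match="transform"):
            run_scheme(SolverConfig(scheme="A"), system_small, g, phantom32)

    def test_log_records_monotone_iterations(self, system_small, phantom32):
        g = forward_project(system_small, phantom32)
        tr = HaarTransform(32)
        log = run_scheme(
            SolverConfig(scheme="C", max_iter=25), system_small, g, phantom32, tr
        )
        assert log.iterations == sorted(log.iterations)
        assert all(e >= 0 for e in log.rre_percent)
        assert isinstance(log, ConvergenceLog)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"scheme": "X"},
            {"p": 0.5},
            {"alpha0": 0.0},
            {"lambda_relax": 2.0},
            {"max_iter": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)
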