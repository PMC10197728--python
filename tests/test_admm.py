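"""ADMM reconstruction: one-shot solves vs dense oracle, TV prox, full loop."""

import numpy as np
import pytest

from cassikit import (
    ALState,
    DenoiserSpec,
    Measurement,
    admm_reconstruct,
    denoise_step,
    guidance_features,
    gram_diagonal,
    initialize_f0,
    projection_step,
    update_multipliers,
)
from cassikit.admm import total_variation, tv_prox
from cassikit.errors import ConfigurationError
from cassikit.sensing import forward_array

from conftest import dense_phi, make_operator


def dense_ratio_solve(op, b, gamma1, gamma2):
    """(gamma2 I + gamma1 Phi^T Phi)^-1 b via an explicit dense solve."""
    Phi = dense_phi(op.mask.values, op.shifts, op.scene_shape)
    n = Phi.shape[1]
    A = gamma2 * np.eye(n) + gamma1 * (Phi.T @ Phi)
    return np.linalg.solve(A, b.ravel()).reshape(b.shape)


def make_state(op, rng, gamma1=1.0, gamma2=1.0):
    shape = (op.n_bands,) + tuple(op.scene_shape)
    return ALState(
        f=rng.normal(size=shape),
        v=rng.normal(size=shape),
        lam1=rng.normal(size=op.detector_shape),
        lam2=rng.normal(size=shape),
        gamma1=gamma1,
        gamma2=gamma2,
    )


class TestInitialization:
    def test_zero_measurement_gives_zero_estimate(self, small_op):
        y = Measurement(np.zeros(small_op.detector_shape))
        assert not initialize_f0(y, small_op, 1.0, 1.0).any()

    def test_matches_dense_solve(self, tiny_op, rng):
        y = Measurement(rng.normal(size=tiny_op.detector_shape))
        Phi = dense_phi(tiny_op.mask.values, tiny_op.shifts, tiny_op.scene_shape)
        b = (Phi.T @ y.values.ravel()).reshape(2, 3, 3)
        expected = dense_ratio_solve(tiny_op, b, 0.7, 1.3)
        assert np.allclose(initialize_f0(y, tiny_op, 0.7, 1.3), expected, atol=1e-8)

    def test_vanishing_data_weight_limit(self, small_op, rng):
        from cassikit.sensing import adjoint_array

        y = Measurement(rng.normal(size=small_op.detector_shape))
        f0 = initialize_f0(y, small_op, 1e-9, 2.0)
        assert np.allclose(f0, adjoint_array(small_op, y.values) / 2.0, atol=1e-6)

    def test_nonpositive_penalties_rejected(self, small_op):
        y = Measurement(np.zeros(small_op.detector_shape))
        with pytest.raises(ValueError):
            initialize_f0(y, small_op, 0.0, 1.0)


class TestProjection:
    def test_truth_is_a_fixed_point(self, small_op, rng):
        f_star = rng.normal(size=(4, 8, 8))
        y = Measurement(forward_array(small_op, f_star))
        state = ALState(
            f=f_star.copy(),
            v=f_star.copy(),
            lam1=np.zeros(small_op.detector_shape),
            lam2=np.zeros_like(f_star),
            gamma1=1.0,
            gamma2=1.0,
        )
        out = projection_step(state, y, small_op)
        assert np.allclose(out, f_star, rtol=1e-10, atol=1e-10)

    def test_vanishing_data_term_returns_shifted_v(self, small_op, rng):
        state = make_state(small_op, rng, gamma1=1e-12, gamma2=1.5)
        state = ALState(
            f=state.f, v=state.v, lam1=np.zeros(small_op.detector_shape),
            lam2=state.lam2, gamma1=1e-12, gamma2=1.5,
        )
        y = Measurement(rng.normal(size=small_op.detector_shape))
        expected = state.v + state.lam2 / state.gamma2
        assert np.allclose(projection_step(state, y, small_op), expected, atol=1e-6)

    def test_matches_dense_solve_8x8x3(self, rng):
        op = make_operator(rows=8, cols=8, n_bands=3)
        state = make_state(op, rng, gamma1=0.8, gamma2=1.7)
        y = Measurement(rng.normal(size=op.detector_shape))
        from cassikit.sensing import adjoint_array

        b = state.lam2 + state.gamma2 * state.v + adjoint_array(
            op, state.gamma1 * y.values - state.lam1
        )
        expected = dense_ratio_solve(op, b, state.gamma1, state.gamma2)
        assert np.allclose(projection_step(state, y, op), expected, atol=1e-8)

    @pytest.mark.parametrize("rows,cols,n_bands", [(3, 3, 2), (8, 8, 3), (12, 12, 4)])
    @pytest.mark.parametrize("seed", range(5))
    def test_one_shot_equals_dense_solve(self, rows, cols, n_bands, seed):
        rng = np.random.default_rng(seed)
        op = make_operator(
            rows=rows + rows % 2, cols=cols + cols % 2, n_bands=n_bands, seed=seed
        )
        state = make_state(op, rng, gamma1=0.5 + seed / 5, gamma2=1.0 + seed / 7)
        y = Measurement(rng.normal(size=op.detector_shape))
        from cassikit.sensing import adjoint_array

        b = state.lam2 + state.gamma2 * state.v + adjoint_array(
            op, state.gamma1 * y.values - state.lam1
        )
        expected = dense_ratio_solve(op, b, state.gamma1, state.gamma2)
        assert np.allclose(projection_step(state, y, op), expected, atol=1e-8)


class TestDenoise:
    def test_zero_strength_tv_is_identity(self, rng):
        u = rng.normal(size=(3, 8, 8))
        spec = DenoiserSpec(kind="tv", strength=0.0)
        assert np.array_equal(denoise_step(u, spec), u)

    def test_constant_cube_is_a_tv_fixed_point(self):
        u = np.full((3, 8, 8), 2.5)
        spec = DenoiserSpec(kind="tv", strength=5.0, max_inner_iters=30)
        assert np.allclose(denoise_step(u, spec), u, atol=1e-12)

    def test_noisy_step_edge_objective_decreases(self, rng):
        # prox output must not raise the denoising objective it minimizes
        edge = np.zeros((1, 16, 16))
        edge[:, :, 8:] = 1.0
        u = edge + 0.15 * rng.normal(size=edge.shape)
        tau = 0.2
        v = tv_prox(u, tau, n_iters=80)
        obj_u = tau * total_variation(u)
        obj_v = tau * total_variation(v) + 0.5 * ((v - u) ** 2).sum()
        assert total_variation(v) < total_variation(u)
        assert obj_v <= obj_u

    def test_identity_kind_returns_input(self, rng):
        u = rng.normal(size=(2, 4, 4))
        assert np.array_equal(denoise_step(u, DenoiserSpec(kind="identity")), u)

    def test_external_denoiser_dispatch(self, rng):
        u = rng.normal(size=(2, 4, 4))
        spec = DenoiserSpec(kind="external", fn=lambda x: x * 0.5)
        assert np.allclose(denoise_step(u, spec), u * 0.5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            DenoiserSpec(kind="wavelet")


class TestGuidance:
    def test_feature_assembly(self, small_op):
        g = guidance_features(2.5, small_op)
        assert np.array_equal(g.gram_trace_map, gram_diagonal(small_op))
        assert np.all(g.gamma_channel == 2.5)
        # band k of the stack is the mask shifted by d_k on the detector grid
        rows, cols = small_op.scene_shape
        for k, d in enumerate(small_op.shifts):
            assert np.array_equal(
                g.shift_mask_stack[k, :, d : d + cols], small_op.mask.values
            )
        # the gram map is the sum of squared stack entries
        assert np.array_equal((g.shift_mask_stack**2).sum(axis=0), g.gram_trace_map)


class TestMultipliers:
    def test_zero_residuals_leave_multipliers_unchanged(self, small_op, rng):
        f = rng.normal(size=(4, 8, 8))
        y = Measurement(forward_array(small_op, f))
        state = ALState(
            f=f, v=f.copy(), lam1=np.ones(small_op.detector_shape),
            lam2=np.ones_like(f), gamma1=1.0, gamma2=1.0,
        )
        new = update_multipliers(state, y, small_op)
        assert np.allclose(new.lam1, state.lam1)
        assert np.allclose(new.lam2, state.lam2)
        assert new.iter == state.iter + 1

    def test_single_step_from_zero(self, small_op, rng):
        state = make_state(small_op, rng, gamma1=0.7)
        state = ALState(
            f=state.f, v=state.v,
            lam1=np.zeros(small_op.detector_shape), lam2=np.zeros_like(state.f),
            gamma1=0.7, gamma2=1.0,
        )
        y = Measurement(rng.normal(size=small_op.detector_shape))
        new = update_multipliers(state, y, small_op)
        expected = -0.7 * (y.values - forward_array(small_op, state.f))
        assert np.allclose(new.lam1, expected)

    def test_two_frozen_updates_double_the_multiplier(self, small_op, rng):
        state = make_state(small_op, rng)
        state = ALState(
            f=state.f, v=state.v,
            lam1=np.zeros(small_op.detector_shape), lam2=np.zeros_like(state.f),
            gamma1=1.0, gamma2=1.0,
        )
        y = Measurement(rng.normal(size=small_op.detector_shape))
        once = update_multipliers(state, y, small_op)
        twice = update_multipliers(once, y, small_op)
        assert np.allclose(twice.lam1, 2 * once.lam1)
        assert np.allclose(twice.lam2, 2 * once.lam2)


class TestFullLoop:
    def test_zero_measurement_reconstructs_zero(self, small_op):
        y = Measurement(np.zeros(small_op.detector_shape))
        cube, diags = admm_reconstruct(y, small_op, DenoiserSpec(kind="tv"), n_iters=5)
        assert not cube.values.any()
        assert max(diags.data_residual) == 0.0

    def test_truth_fixed_point_with_perfect_denoiser(self, small_op, rng):
        # noiseless data + a denoiser that returns the truth: one full
        # iteration leaves the truth invariant
        f_star = rng.normal(size=(4, 8, 8))
        y = Measurement(forward_array(small_op, f_star))
        spec = DenoiserSpec(kind="external", fn=lambda u: f_star.copy())
        cube, diags = admm_reconstruct(y, small_op, spec, n_iters=3)
        assert np.allclose(cube.values, f_star, atol=1e-8)
        assert diags.data_residual[-1] < 1e-8

    def test_final_data_residual_not_above_first(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            op = make_operator(rows=16, cols=16, n_bands=3, seed=seed)
            f = np.abs(rng.normal(size=(3, 16, 16)))
            y = Measurement(forward_array(op, f))
            _, diags = admm_reconstruct(y, op, DenoiserSpec(kind="tv"), n_iters=10)
            assert diags.data_residual[-1] <= diags.data_residual[0] + 1e-12

    def test_doubling_data_penalty_does_not_raise_residual(self):
        # noiseless data: a heavier data weight can only tighten consistency
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            op = make_operator(rows=16, cols=16, n_bands=3, seed=seed)
            f = np.abs(rng.normal(size=(3, 16, 16)))
            y = Measurement(forward_array(op, f))
            _, d1 = admm_reconstruct(y, op, DenoiserSpec(kind="tv"), n_iters=15, gamma1=1.0)
            _, d2 = admm_reconstruct(y, op, DenoiserSpec(kind="tv"), n_iters=15, gamma1=2.0)
            assert d2.data_residual[-1] <= d1.data_residual[-1] + 1e-9

    def test_reconstruction_improves_on_initialization(self, rng):
        from cassikit import PhantomConfig, eye_phantom, psnr

        cube = eye_phantom(PhantomConfig(kind="eye", rows=32, cols=32, n_bands=4, seed=2))
        op = make_operator(rows=32, cols=32, n_bands=4, seed=5)
        y = Measurement(forward_array(op, cube.values))
        f0 = initialize_f0(y, op, 1.0, 1.0)
        rec, _ = admm_reconstruct(y, op, DenoiserSpec(kind="tv"), n_iters=30)
        assert psnr(rec.values, cube.values) > psnr(f0, cube.values) + 5.0

    def test_clamp_produces_nonnegative_output(self, small_op, rng):
        y = Measurement(np.abs(rng.normal(size=small_op.detector_shape)))
        cube, _ = admm_reconstruct(
            y, small_op, DenoiserSpec(kind="tv"), n_iters=5, clamp_nonneg=True
        )
        assert cube.values.min() >= 0.0
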