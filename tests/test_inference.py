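"""Tests of per-step MAP inference and sequence filtering."""

import numpy as np
import pytest

from dpcnet.inference import (
    InferenceOptions,
    filter_sequence,
    infer_first_step,
    infer_step,
)
from dpcnet.model import (
    DPCParameters,
    Hyperparameters,
    ModelShape,
    random_parameters,
    sample_generative,
    step_loss_grads,
)


@pytest.fixture
def tiny():
    rng = np.random.default_rng(0)
    shape = ModelShape(M=6, N=4, N_h=2, K=2, hypernet_layers=(4,))
    params = random_parameters(shape, rng, v_spectral_radius=0.5, v_identity_bias=0.7)
    hyper = Hyperparameters(sigma2=0.5, sigma_r2=0.5, lambda_sparse=0.05, lambda_h=0.01)
    return params, hyper


class TestFirstStep:
    def test_zero_input_with_sparse_prior_stays_zero(self, tiny):
        params, hyper = tiny
        r0, _ = infer_first_step(np.zeros(6), params, hyper)
        assert np.array_equal(r0, np.zeros(4))

    def test_scalar_least_squares_closed_form(self):
        params = DPCParameters(
            U=np.array([[1.0]]), V=np.eye(1)[None],
            theta=[(np.zeros((1, 1)), np.zeros(1))],
        )
        hyper = Hyperparameters(sigma2=1.0, lambda_sparse=0.0)
        opts = InferenceOptions(lr_r=0.5, max_iters=500, tol=1e-10)
        r0, _ = infer_first_step(np.array([1.7]), params, hyper, opts)
        assert np.isclose(r0[0], 1.7, atol=1e-6)

    def test_lasso_zero_solution_condition(self, tiny):
        """lambda >= ||U^T I||_inf / sigma2 forces the all-zero solution."""

        params, _ = tiny
        rng = np.random.default_rng(3)
        I0 = rng.standard_normal(6)
        sigma2 = 0.8
        lam_crit = np.max(np.abs(params.U.T @ I0)) / sigma2
        hyper = Hyperparameters(sigma2=sigma2, lambda_sparse=lam_crit * 1.01)
        r0, _ = infer_first_step(I0, params, hyper, InferenceOptions(max_iters=400))
        assert np.allclose(r0, 0.0)
        # brute-force 1-D scan: moving any single coordinate increases loss
        from dpcnet.model import first_step_loss

        base = first_step_loss(I0, np.zeros(4), params, hyper)
        for i in range(4):
            for v in np.linspace(-0.5, 0.5, 21):
                e = np.zeros(4)
                e[i] = v
                assert first_step_loss(I0, e, params, hyper) >= base - 1e-12

    def test_loss_non_increasing(self, tiny):
        params, hyper = tiny
        I0 = np.random.default_rng(5).standard_normal(6)
        _, diag = infer_first_step(I0, params, hyper)
        losses = diag["loss"][:, 0]
        assert np.all(np.diff(losses) <= 1e-10)


class TestInferStep:
    def test_self_consistency_with_true_higher_state(self, tiny):
        """On noiseless model-generated data with the true r_h supplied and
        no sparsity, the corrected estimate recovers the true state."""

        params, _ = tiny
        hyper = Hyperparameters(sigma2=0.5, sigma_r2=0.5, lambda_sparse=0.0, lambda_h=0.0)
        frames, lat = sample_generative(params, T=3, rng=11, n_sequences=1)
        opts = InferenceOptions(lr_r=0.2, lr_rh=1e-9, max_iters=2000, tol=1e-12)
        r_t, _, _, _ = infer_step(frames[0, 1], lat["r"][0, 0], lat["r_h"][0], params, hyper, opts)
        assert np.max(np.abs(r_t - lat["r"][0, 1])) < 1e-4

    def test_term_dropping_matches_first_step(self, tiny):
        """With the temporal term off and lambda_h = 0, a step reduces to
        first-step inference on the same frame."""

        params, _ = tiny
        hyper = Hyperparameters(sigma2=0.5, sigma_r2=1e12, lambda_sparse=0.05, lambda_h=0.0)
        I = np.random.default_rng(6).standard_normal(6)
        opts = InferenceOptions(lr_r=0.1, lr_rh=1e-9, max_iters=500, tol=1e-9)
        r_t, _, _, _ = infer_step(I, np.zeros(4), np.zeros(2), params, hyper, opts)
        hyper0 = Hyperparameters(sigma2=0.5, lambda_sparse=0.05)
        r_first, _ = infer_first_step(I, params, hyper0, opts)
        assert np.allclose(r_t, r_first, atol=1e-4)

    def test_rh_moves_downhill(self, tiny):
        """A single step changes r_h along the negative analytic gradient."""

        params, hyper = tiny
        rng = np.random.default_rng(7)
        I = rng.standard_normal(6)
        r_prev = np.abs(rng.standard_normal(4))
        rh = rng.standard_normal(2) * 0.5
        from dpcnet.model import hypernet_forward, mix_transitions, transition_mean

        r_start = transition_mean(r_prev, mix_transitions(hypernet_forward(rh, params.theta), params.V))
        g = step_loss_grads(I, r_start, rh, r_prev, params, hyper)
        opts = InferenceOptions(lr_r=1e-12, lr_rh=1e-4, max_iters=1, tol=0.0, backtracking=False)
        _, rh_new, _, _ = infer_step(I, r_prev, rh, params, hyper, opts)
        moved = rh_new - rh
        grad_dir = -g["r_h"] / np.linalg.norm(g["r_h"])
        # r was warm-started at r_bar, matching the gradient evaluation point
        assert np.dot(moved / np.linalg.norm(moved), grad_dir) > 0.99

    def test_loss_non_increasing_with_backtracking(self, tiny):
        params, hyper = tiny
        rng = np.random.default_rng(8)
        I = rng.standard_normal(6)
        opts = InferenceOptions(lr_r=0.5, lr_rh=0.5, max_iters=60, tol=0.0)
        _, _, _, diag = infer_step(I, rng.standard_normal(4), rng.standard_normal(2), params, hyper, opts)
        losses = diag["loss"][:, 0]
        assert np.all(np.diff(losses) <= 1e-10)


class TestFilterSequence:
    def test_all_zero_sequence(self, tiny):
        params, hyper = tiny
        frames = np.zeros((1, 5, 6))
        traj = filter_sequence(frames, params, hyper)
        assert np.allclose(traj.r_hat, 0.0)
        assert np.allclose(traj.pred_err[:, 1:], 0.0, atol=1e-8)
        assert np.array_equal(traj.r_bar[:, 0], np.zeros((1, 4)))

    def test_model_generated_errors_shrink_after_adaptation(self, tiny):
        params, hyper = tiny
        frames, _ = sample_generative(params, T=10, rng=21, n_sequences=8)
        opts = InferenceOptions(lr_r=0.1, lr_rh=0.05, max_iters=150, tol=1e-6)
        traj = filter_sequence(frames, params, hyper, opts)
        err = traj.pred_err.mean(axis=0)
        assert np.all(err[2:] < 0.5 * err[1])

    def test_causality_prefix_invariance(self, tiny):
        params, hyper = tiny
        frames, _ = sample_generative(params, T=8, rng=22, n_sequences=3)
        full = filter_sequence(frames, params, hyper)
        prefix = filter_sequence(frames[:, :5], params, hyper)
        assert np.array_equal(full.r_hat[:, :5], prefix.r_hat)
        assert np.array_equal(full.r_h_hat[:, :5], prefix.r_h_hat)

    def test_direction_of_time_matters(self, tiny):
        params, hyper = tiny
        frames, _ = sample_generative(params, T=6, rng=23, n_sequences=1)
        fwd = filter_sequence(frames, params, hyper)
        bwd = filter_sequence(frames[:, ::-1], params, hyper)
        assert not np.allclose(fwd.r_hat, bwd.r_hat[:, ::-1])

    def test_w_recovery_on_small_model(self):
        """Inferred mixing weights align with the truth after adaptation."""

        from dpcnet.experiments import w_recovery_experiment

        res = w_recovery_experiment(seed=5, n_sequences=30)
        assert res["median_cosine"] > 0.9

    def test_divergence_raises_named_error(self, tiny):
        from dpcnet.inference import NumericalDivergenceError

        params, hyper = tiny
        frames = 1e150 * np.ones((1, 2, 6))
        opts = InferenceOptions(lr_r=1e6, max_iters=10, backtracking=False)
        with pytest.raises(NumericalDivergenceError):
            filter_sequence(frames, params, hyper, opts)
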