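"""Unit tests for the generative model's types, forward ops and losses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dpcnet.model import (
    DPCParameters,
    Hyperparameters,
    ModelShape,
    decode_image,
    first_step_loss,
    first_step_loss_grads,
    hypernet_forward,
    mix_transitions,
    random_parameters,
    sample_generative,
    step_loss,
    step_loss_grads,
    step_loss_joint,
    transition_mean,
)


@pytest.fixture
def small_params():
    rng = np.random.default_rng(7)
    shape = ModelShape(M=6, N=4, N_h=3, K=2, hypernet_layers=(5,))
    return random_parameters(shape, rng)


class TestTypes:
    def test_shape_rejects_nonpositive_dims(self):
        with pytest.raises(ValueError):
            ModelShape(M=0, N=4, N_h=2, K=1)
        with pytest.raises(ValueError):
            ModelShape(M=4, N=4, N_h=2, K=-1)

    def test_hyperparameters_reject_bad_variances(self):
        with pytest.raises(ValueError):
            Hyperparameters(sigma2=0.0)
        with pytest.raises(ValueError):
            Hyperparameters(sigma_r2=-1.0)
        with pytest.raises(ValueError):
            Hyperparameters(lambda_sparse=-0.1)

    def test_parameters_validate_consistency(self):
        with pytest.raises(ValueError):
            DPCParameters(
                U=np.zeros((4, 3)), V=np.zeros((2, 5, 5)),
                theta=[(np.zeros((2, 2)), np.zeros(2))],
            )
        with pytest.raises(ValueError):
            DPCParameters(
                U=np.full((4, 3), np.nan), V=np.zeros((2, 3, 3)),
                theta=[(np.zeros((2, 2)), np.zeros(2))],
            )


class TestHypernet:
    def test_zero_weights_return_bias(self):
        b = np.array([0.3, -1.2])
        theta = [(np.zeros((2, 3)), b)]
        for rh in (np.zeros(3), np.array([1.0, -2.0, 0.5])):
            assert np.allclose(hypernet_forward(rh, theta), b)

    def test_two_layer_hand_evaluation(self):
        # w = W2 tanh(W1 rh + b1) + b2 evaluated by hand
        W1 = np.array([[1.0, 0.5], [-0.5, 2.0]])
        b1 = np.array([0.1, -0.2])
        W2 = np.array([[2.0, -1.0], [0.0, 1.0]])
        b2 = np.array([0.5, 0.0])
        rh = np.array([1.0, -1.0])
        hidden = np.tanh(W1 @ rh + b1)
        expected = W2 @ hidden + b2
        got = hypernet_forward(rh, [(W1, b1), (W2, b2)])
        assert np.allclose(got, expected)

    def test_shape_mismatch_raises(self, small_params):
        with pytest.raises(ValueError):
            hypernet_forward(np.zeros(5), small_params.theta)

    def test_batched_matches_loop(self, small_params):
        rng = np.random.default_rng(0)
        RH = rng.standard_normal((4, 3))
        batched = hypernet_forward(RH, small_params.theta)
        for b in range(4):
            assert np.allclose(batched[b], hypernet_forward(RH[b], small_params.theta))


class TestMixTransitions:
    def test_one_hot_selects_matrix(self):
        rng = np.random.default_rng(1)
        V = rng.standard_normal((5, 3, 3))
        w = np.zeros(5)
        w[3] = 1.0
        assert np.array_equal(mix_transitions(w, V), V[3])

    def test_zero_weights_give_zero_matrix(self):
        V = np.random.default_rng(2).standard_normal((4, 3, 3))
        assert np.array_equal(mix_transitions(np.zeros(4), V), np.zeros((3, 3)))

    def test_hand_computed_mean(self):
        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        B = np.array([[5.0, 6.0], [7.0, 8.0]])
        got = mix_transitions(np.array([0.5, 0.5]), np.stack([A, B]))
        assert np.allclose(got, np.array([[3.0, 4.0], [5.0, 6.0]]))

    def test_k_mismatch_raises(self):
        with pytest.raises(ValueError):
            mix_transitions(np.ones(3), np.zeros((2, 4, 4)))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_linearity(self, seed):
        rng = np.random.default_rng(seed)
        V = rng.standard_normal((3, 4, 4))
        w1, w2 = rng.standard_normal((2, 3))
        a, b = rng.standard_normal(2)
        left = mix_transitions(a * w1 + b * w2, V)
        right = a * mix_transitions(w1, V) + b * mix_transitions(w2, V)
        assert np.allclose(left, right, atol=1e-12)


class TestTransitionMean:
    def test_relu_clips_negative_entries(self):
        got = transition_mean(np.array([1.0, -2.0, 3.0]), np.eye(3))
        assert np.array_equal(got, [1.0, 0.0, 3.0])

    def test_negative_identity_kills_nonnegative_state(self):
        got = transition_mean(np.array([0.5, 0.0, 2.0]), -np.eye(3))
        assert np.array_equal(got, np.zeros(3))

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        V = rng.standard_normal((3, 3))
        r = rng.standard_normal(3)
        oracle = np.array([max(sum(V[i, j] * r[j] for j in range(3)), 0.0) for i in range(3)])
        assert np.allclose(transition_mean(r, V), oracle)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            transition_mean(np.zeros(4), np.eye(3))


class TestDecodeImage:
    def test_zero_state_gives_zero_frame(self, small_params):
        assert np.array_equal(decode_image(np.zeros(4), small_params.U), np.zeros(6))

    def test_one_hot_extracts_column(self, small_params):
        r = np.zeros(4)
        r[2] = 1.0
        assert np.allclose(decode_image(r, small_params.U), small_params.U[:, 2])

    def test_matches_matvec(self, small_params):
        rng = np.random.default_rng(4)
        r = rng.standard_normal(4)
        assert np.allclose(decode_image(r, small_params.U), small_params.U @ r)


class TestLosses:
    def test_all_zero_inputs_give_zero_loss(self, small_params):
        hyper = Hyperparameters(lambda_sparse=1.0, lambda_h=1.0)
        z4, z3, z6 = np.zeros(4), np.zeros(3), np.zeros(6)
        assert step_loss(z6, z4, z4, z3, small_params, hyper) == 0.0
        assert first_step_loss(z6, z4, small_params, hyper) == 0.0

    def test_scalar_arithmetic_step_loss(self):
        params = DPCParameters(
            U=np.array([[1.0]]), V=np.eye(1)[None],
            theta=[(np.zeros((1, 1)), np.zeros(1))],
        )
        hyper = Hyperparameters(sigma2=1.0, sigma_r2=1.0, lambda_sparse=1.0, lambda_h=1.0)
        got = step_loss(
            np.array([2.0]), np.array([1.0]), np.array([0.0]), np.array([1.0]), params, hyper
        )
        # 0.5*(2-1)^2 + 0.5*(1-0)^2 + |1| + 1^2 = 3
        assert np.isclose(got, 3.0)

    def test_scalar_arithmetic_first_step(self):
        params = DPCParameters(
            U=np.array([[2.0]]), V=np.eye(1)[None],
            theta=[(np.zeros((1, 1)), np.zeros(1))],
        )
        hyper = Hyperparameters(sigma2=1.0, lambda_sparse=0.5)
        got = first_step_loss(np.array([4.0]), np.array([1.0]), params, hyper)
        # 0.5*(4-2)^2 + 0.5*1 = 2.5
        assert np.isclose(got, 2.5)

    def test_first_step_is_term_dropping_limit(self, small_params):
        rng = np.random.default_rng(5)
        I = rng.standard_normal(6)
        r = rng.standard_normal(4)
        hyper_inf = Hyperparameters(sigma2=0.7, sigma_r2=1e12, lambda_sparse=0.3, lambda_h=0.0)
        hyper_first = Hyperparameters(sigma2=0.7, lambda_sparse=0.3)
        full = step_loss(I, r, np.zeros(4), np.zeros(3), small_params, hyper_inf)
        reduced = first_step_loss(I, r, small_params, hyper_first)
        assert np.isclose(full, reduced, atol=1e-9)

    def test_permutation_invariance(self, small_params):
        """Simultaneously permuting latent indices leaves the loss unchanged."""

        rng = np.random.default_rng(6)
        hyper = Hyperparameters(sigma2=0.8, sigma_r2=1.1, lambda_sparse=0.2, lambda_h=0.1)
        I = rng.standard_normal(6)
        r, r_bar = rng.standard_normal((2, 4))
        rh = rng.standard_normal(3)
        perm = np.random.default_rng(8).permutation(4)
        permuted = DPCParameters(
            U=small_params.U[:, perm], V=small_params.V, theta=small_params.theta
        )
        base = step_loss(I, r, r_bar, rh, small_params, hyper)
        after = step_loss(I, r[perm], r_bar[perm], rh, permuted, hyper)
        assert np.isclose(base, after, atol=1e-12)

    def test_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError):
            Hyperparameters(sigma2=-1.0)


class TestGradients:
    """Analytic gradients vs central finite differences (the loss oracle)."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_step_loss_gradients_match_fd(self, seed):
        rng = np.random.default_rng(seed)
        shape = ModelShape(M=5, N=4, N_h=3, K=2, hypernet_layers=(4,))
        params = random_parameters(shape, rng)
        hyper = Hyperparameters(sigma2=0.6, sigma_r2=1.2, lambda_sparse=0.1, lambda_h=0.2)
        I = rng.standard_normal(5)
        r = rng.standard_normal(4) + 0.5  # away from L1 kinks at 0
        rh = rng.standard_normal(3)
        rp = rng.standard_normal(4)
        g = step_loss_grads(I, r, rh, rp, params, hyper)
        eps = 1e-6

        def L(r_=None, rh_=None):
            return step_loss_joint(
                I, r if r_ is None else r_, rh if rh_ is None else rh_, rp, params, hyper
            )

        for vec, grad, which in ((r, g["r"], "r"), (rh, g["r_h"], "rh")):
            fd = np.zeros_like(vec)
            for i in range(len(vec)):
                e = np.zeros_like(vec)
                e[i] = eps
                if which == "r":
                    fd[i] = (L(r_=vec + e) - L(r_=vec - e)) / (2 * eps)
                else:
                    fd[i] = (L(rh_=vec + e) - L(rh_=vec - e)) / (2 * eps)
            assert np.max(np.abs(fd - grad)) / max(1.0, np.max(np.abs(fd))) < 1e-5

        for arr, grad in ((params.U, g["U"]), (params.V, g["V"])):
            fd = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                arr[idx] += eps
                lp = L()
                arr[idx] -= 2 * eps
                lm = L()
                arr[idx] += eps
                fd[idx] = (lp - lm) / (2 * eps)
            assert np.max(np.abs(fd - grad)) / max(1.0, np.max(np.abs(fd))) < 1e-5

        for layer, (dW, db) in enumerate(g["theta"]):
            for arr, grad in ((params.theta[layer][0], dW), (params.theta[layer][1], db)):
                fd = np.zeros_like(arr)
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    arr[idx] += eps
                    lp = L()
                    arr[idx] -= 2 * eps
                    lm = L()
                    arr[idx] += eps
                    fd[idx] = (lp - lm) / (2 * eps)
                assert np.max(np.abs(fd - grad)) / max(1.0, np.max(np.abs(fd))) < 1e-5

    def test_first_step_gradients_match_fd(self, small_params):
        rng = np.random.default_rng(11)
        hyper = Hyperparameters(sigma2=0.9, lambda_sparse=0.15)
        I = rng.standard_normal(6)
        r = rng.standard_normal(4) + 0.4
        g = first_step_loss_grads(I, r, small_params, hyper)
        eps = 1e-6
        fd = np.zeros_like(r)
        for i in range(4):
            e = np.zeros(4)
            e[i] = eps
            fd[i] = (
                first_step_loss(I, r + e, small_params, hyper)
                - first_step_loss(I, r - e, small_params, hyper)
            ) / (2 * eps)
        assert np.max(np.abs(fd - g["r"])) < 1e-5


class TestSampling:
    def test_noiseless_identity_mix_is_fixed_point(self):
        # With V_k = I for all k and hypernet output summing to 1, the
        # nonnegative initial state is reproduced at every step.
        shape = ModelShape(M=4, N=3, N_h=2, K=2, hypernet_layers=())
        theta = [(np.zeros((2, 2)), np.array([0.5, 0.5]))]
        rng = np.random.default_rng(0)
        U = rng.standard_normal((4, 3))
        params = DPCParameters(U=U, V=np.stack([np.eye(3), np.eye(3)]), theta=theta)
        frames, lat = sample_generative(params, T=5, rng=3, n_sequences=2)
        r0 = np.abs(lat["r"][:, 0])  # may contain negatives; use ReLU fix-point subset
        # after one step states are nonnegative and then constant
        assert np.allclose(lat["r"][:, 2], lat["r"][:, 1])
        assert np.allclose(frames[:, 2], frames[:, 1])

    def test_same_seed_bit_identical(self, small_params):
        f1, l1 = sample_generative(small_params, T=6, rng=42, n_sequences=3, sigma2=0.1, sigma_r2=0.1)
        f2, l2 = sample_generative(small_params, T=6, rng=42, n_sequences=3, sigma2=0.1, sigma_r2=0.1)
        assert np.array_equal(f1, f2)
        assert np.array_equal(l1["r_h"], l2["r_h"])

    def test_pixel_noise_variance_matches(self, small_params):
        sigma2 = 0.04
        frames, lat = sample_generative(
            small_params, T=2, rng=9, n_sequences=5000, sigma2=sigma2, sigma_r2=0.0
        )
        clean = np.einsum("mn,btn->btm", small_params.U, lat["r"])
        noise = frames - clean
        assert abs(noise.var() - sigma2) / sigma2 < 0.05

    def test_zero_noise_decodes_exactly(self, small_params):
        frames, lat = sample_generative(small_params, T=4, rng=2, n_sequences=2)
        recon = decode_image(lat["r"], small_params.U)
        assert np.allclose(frames, recon, atol=1e-12)
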