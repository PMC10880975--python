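"""Tests of the associative memory: ridge-oracle equivalence, Hebbian
storage, cue-triggered recall and the cross-correlation analysis."""

import numpy as np
import pytest

from dpcnet.memory import (
    CrossCorrResult,
    MemoryParameters,
    crosscorr_difference_slope,
    init_memory,
    memory_infer,
    memory_store,
    peak_lag_slope,
    recall_from_cue,
    rf_distance_crosscorr,
    rf_positions,
    rollout_recall,
)
from dpcnet.model import DPCParameters


def ridge(G, s, lam):
    P = G.shape[1]
    return np.linalg.solve(G.T @ G + lam * np.eye(P), G.T @ s)


class TestMemoryInfer:
    def test_zero_synapses_zero_memory(self):
        m = memory_infer(np.ones(4), np.zeros((4, 3)), 0.5)
        assert np.array_equal(m, np.zeros(3))

    def test_identity_synapses_halve_target(self):
        s = np.array([1.0, -2.0, 0.5])
        m = memory_infer(s, np.eye(3), 1.0)
        assert np.allclose(m, s / 2, atol=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_closed_form_ridge(self, seed):
        rng = np.random.default_rng(seed)
        D, P = rng.integers(3, 20), rng.integers(2, 50)
        G = rng.standard_normal((D, P))
        s = rng.standard_normal(D)
        m = memory_infer(s, G, 0.1)
        assert np.max(np.abs(m - ridge(G, s, 0.1))) < 1e-4


class TestMemoryStore:
    def test_reconstruction_error_decreases_over_repetitions(self):
        rng = np.random.default_rng(1)
        mem = init_memory(10, 8, rng=2, eta_G=0.05)
        r0, rh = rng.standard_normal(6), rng.standard_normal(4)
        _, errors = memory_store(mem, r0, rh, n_reps=5)
        assert np.all(np.diff(errors) < 0)

    def test_zero_rate_leaves_synapses(self):
        rng = np.random.default_rng(2)
        mem = init_memory(8, 8, rng=3)
        out, _ = memory_store(mem, rng.standard_normal(5), rng.standard_normal(3), eta_G=0.0)
        assert np.array_equal(out.G, mem.G)

    def test_single_pattern_converges_to_target(self):
        rng = np.random.default_rng(3)
        mem = init_memory(9, 9, rng=4, eta_G=0.2, lambda_m=0.01)
        r0, rh = rng.standard_normal(5), rng.standard_normal(4)
        out, _ = memory_store(mem, r0, rh, n_reps=60)
        s = np.concatenate([r0, rh])
        m = memory_infer(s, out.G, out.lambda_m)
        assert np.linalg.norm(s - out.G @ m) / np.linalg.norm(s) < 0.05


class TestRecall:
    def test_zero_cue_recalls_nothing(self):
        mem = init_memory(8, 8, rng=5, lambda_m=0.5)
        m, rh = recall_from_cue(mem, np.zeros(5), 5)
        assert np.allclose(m, 0.0) and np.allclose(rh, 0.0)

    def test_single_pattern_completion(self):
        rng = np.random.default_rng(6)
        mem = init_memory(9, 9, rng=7, eta_G=0.2, lambda_m=0.01)
        r0, rh = rng.standard_normal(5), rng.standard_normal(4)
        mem, _ = memory_store(mem, r0, rh, n_reps=60)
        _, rh_rec = recall_from_cue(mem, r0, 5)
        cos = rh_rec @ rh / (np.linalg.norm(rh_rec) * np.linalg.norm(rh))
        assert cos > 0.9

    def test_two_orthogonal_patterns_are_cue_specific(self):
        rng = np.random.default_rng(8)
        r0_a = np.array([1.0, 0, 0, 0, 0.5, 0])
        r0_b = np.array([0, 0, 1.0, 0, 0, -0.5])  # orthogonal content codes
        rh_a = rng.standard_normal(4)
        rh_b = rng.standard_normal(4)
        mem = init_memory(10, 10, rng=9, eta_G=0.2, lambda_m=0.01)
        mem, _ = memory_store(mem, r0_a, rh_a, n_reps=40)
        mem, _ = memory_store(mem, r0_b, rh_b, n_reps=40)

        def cos(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12)

        _, rec_a = recall_from_cue(mem, r0_a, 6)
        _, rec_b = recall_from_cue(mem, r0_b, 6)
        assert cos(rec_a, rh_a) > cos(rec_a, rh_b)
        assert cos(rec_b, rh_b) > cos(rec_b, rh_a)


class TestRollout:
    def test_single_step_returns_decoded_cue(self):
        rng = np.random.default_rng(10)
        U = rng.standard_normal((6, 4))
        params = DPCParameters(
            U=U, V=np.stack([np.eye(4)] * 2),
            theta=[(np.zeros((2, 3)), np.full(2, 0.5))],
        )
        r0 = rng.standard_normal(4)
        frames, resp = rollout_recall(params, r0, np.zeros(3), T=1)
        assert np.allclose(frames[0], U @ r0)
        assert np.array_equal(resp[0], r0)

    def test_identity_dynamics_repeat_nonnegative_state(self):
        rng = np.random.default_rng(11)
        U = rng.standard_normal((6, 4))
        params = DPCParameters(
            U=U, V=np.stack([np.eye(4)] * 2),
            theta=[(np.zeros((2, 3)), np.full(2, 0.5))],
        )
        r0 = np.abs(rng.standard_normal(4))
        frames, resp = rollout_recall(params, r0, np.zeros(3), T=4)
        assert np.allclose(resp, r0)


class TestCrossCorrelation:
    def _params_with_pixel_filters(self, N, side):
        # neuron i's filter is a single pixel on the middle row, column i
        U = np.zeros((side * side, N))
        for i in range(N):
            U[(side // 2) * side + i, i] = 1.0
        return DPCParameters(
            U=U, V=np.stack([np.eye(N)] * 2),
            theta=[(np.zeros((2, 2)), np.full(2, 0.5))],
        )

    def test_identical_series_peak_at_zero(self):
        params = self._params_with_pixel_filters(2, 8)
        t = np.arange(12.0)
        resp = np.stack([np.sin(t), np.sin(t)], axis=1)
        res = rf_distance_crosscorr(resp, params.U, (8, 8), max_lag=3)
        assert len(res.pairs) == 1
        assert res.pairs["peak_lag"][0] == 0
        assert np.isclose(res.pairs["peak_corr"][0], 1.0)

    def test_shifted_series_peak_at_shift(self):
        params = self._params_with_pixel_filters(2, 8)
        base = np.exp(-0.5 * ((np.arange(16.0) - 5) / 1.5) ** 2)
        resp = np.stack([base, np.roll(base, 2)], axis=1)
        res = rf_distance_crosscorr(resp, params.U, (8, 8), max_lag=3)
        assert res.pairs["peak_lag"][0] == 2

    def test_traveling_wave_slope_recovered(self):
        side, N = 12, 6
        U = np.zeros((side * side, N))
        for i in range(N):
            U[(side // 2) * side + 2 * i, i] = 1.0  # RFs spaced 2 px apart
        params = DPCParameters(
            U=U, V=np.stack([np.eye(N)] * 2),
            theta=[(np.zeros((2, 2)), np.full(2, 0.5))],
        )
        lag_per_px = 0.5  # one time step per 2 px
        t = np.arange(30.0)
        resp = np.stack(
            [np.exp(-0.5 * ((t - 8 - lag_per_px * 2 * i) / 1.2) ** 2) for i in range(N)],
            axis=1,
        )
        res = rf_distance_crosscorr(resp, U, (side, side), max_lag=8)
        slope = peak_lag_slope(res)
        assert abs(slope - lag_per_px) / lag_per_px < 0.2

    def test_zero_filter_neurons_excluded(self):
        params = self._params_with_pixel_filters(3, 8)
        params.U[:, 2] = 0.0
        resp = np.random.default_rng(12).standard_normal((10, 3))
        res = rf_distance_crosscorr(resp, params.U, (8, 8), max_lag=2)
        assert res.n_excluded == 1

    def test_difference_slope_of_constructed_wave(self):
        side, N = 12, 5
        U = np.zeros((side * side, N))
        for i in range(N):
            U[(side // 2) * side + 2 * i, i] = 1.0
        t = np.arange(20.0)
        rng = np.random.default_rng(13)
        flat = 0.05 * rng.standard_normal((20, N)) + 1.0
        wave = np.stack(
            [np.exp(-0.5 * ((t - 5 - i) / 1.0) ** 2) for i in range(N)], axis=1
        )
        before = rf_distance_crosscorr(flat, U, (side, side), max_lag=6)
        after = rf_distance_crosscorr(wave, U, (side, side), max_lag=6)
        assert crosscorr_difference_slope(before, after) > 0


class TestParameterValidation:
    def test_memory_parameters_validate(self):
        with pytest.raises(ValueError):
            MemoryParameters(G=np.zeros((4, 3)), eta_G=0.0)
        with pytest.raises(ValueError):
            MemoryParameters(G=np.zeros(4), eta_G=0.1)
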