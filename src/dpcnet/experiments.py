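"""Desk-scale experiment protocols.

Each function runs one of the package's experiment families end to end on
synthetic stimuli and returns a dict of scalar results.  The default sizes
are the package's study conditions: large enough for the qualitative
signatures (timescale hierarchy, factored representations, flash-lag
structure, cue-triggered recall, three-level abstraction) to be measured,
small enough to run on a single CPU in minutes.  Tests, the acceptance
script and the CLI all call these entry points.
"""

from __future__ import annotations

import numpy as np

from .analysis import autocorrelation, crossval_decode, fit_exponential_decay
from .datasets import (
    DIRECTION_NAMES,
    SpriteDatasetSpec,
    make_bouncing_dataset,
    make_moving_sprites,
    make_white_noise,
)
from .estimators import DynamicPredictiveCoder, EpisodicMemory, ThreeLevelDynamicPredictiveCoder
from .flashlag import flash_lag_table, latency_sweep, select_consistent_sequences
from .inference import InferenceOptions, filter_sequence
from .memory import rf_distance_crosscorr, crosscorr_difference_slope
from .model import Hyperparameters, ModelShape, random_parameters, sample_generative
from .training import TrainingOptions, train_two_level

__all__ = [
    "make_teacher",
    "TEACHER_HYPER",
    "w_recovery_experiment",
    "teacher_student_experiment",
    "sprite_corpus",
    "train_sprite_coder",
    "timescale_experiment",
    "factorization_experiment",
    "flashlag_experiment",
    "recall_experiment",
    "train_bounce_model",
    "threelevel_experiment",
]


# ---------------------------------------------------------------------------
# Generative self-consistency (teacher-student)
# ---------------------------------------------------------------------------

TEACHER_HYPER = Hyperparameters(sigma2=0.5, sigma_r2=0.5, lambda_sparse=0.01, lambda_h=0.01)


def make_teacher(
    seed: int, M: int = 16, N: int = 8, N_h: int = 2, K: int = 2, hidden: tuple[int, ...] = (8,)
):
    """Random small teacher with smooth (near-identity) dynamics."""

    shape = ModelShape(M=M, N=N, N_h=N_h, K=K, hypernet_layers=hidden)
    rng = np.random.default_rng(seed)
    return random_parameters(shape, rng, v_spectral_radius=0.5, v_identity_bias=0.7)


def w_recovery_experiment(seed: int, n_sequences: int = 50, T: int = 12) -> dict:
    """Filter teacher-sampled sequences with the true parameters and compare
    the inferred mixing weights to the true ones (cosine similarity)."""

    teacher = make_teacher(seed)
    frames, latents = sample_generative(
        teacher, T=T, rng=seed + 1, n_sequences=n_sequences, sigma2=1e-4, sigma_r2=1e-4
    )
    opts = InferenceOptions(lr_r=0.1, lr_rh=0.05, max_iters=200, tol=1e-6)
    traj = filter_sequence(frames, teacher, TEACHER_HYPER, opts)
    w_true, w_inf = latents["w"], traj.w[:, -1]
    cos = np.sum(w_true * w_inf, axis=1) / (
        np.linalg.norm(w_true, axis=1) * np.linalg.norm(w_inf, axis=1) + 1e-12
    )
    return {
        "mean_cosine": float(cos.mean()),
        "median_cosine": float(np.median(cos)),
        "frac_above_0.9": float((cos > 0.9).mean()),
    }


def teacher_student_experiment(
    seed: int, n_train: int = 400, n_test: int = 50, epochs: int = 100, lr: float = 0.003
) -> dict:
    """Train a student from scratch on teacher-sampled sequences and measure
    held-out one-step image-prediction R^2 (steps past the adaptation
    transient, t >= 2).  The conservative learning rate matters: at higher
    rates the student's late training can destabilize on some teachers."""

    teacher = make_teacher(seed)
    shape = teacher.shape
    train, _ = sample_generative(
        teacher, T=10, rng=seed + 1, n_sequences=n_train, sigma2=1e-4, sigma_r2=1e-4
    )
    test, _ = sample_generative(
        teacher, T=10, rng=seed + 2, n_sequences=n_test, sigma2=1e-4, sigma_r2=1e-4
    )
    opts = TrainingOptions(
        epochs=epochs, batch_size=64, lr=lr,
        infer=InferenceOptions(lr_r=0.1, lr_rh=0.05, max_iters=30, tol=1e-4),
    )
    student, hist = train_two_level(train, shape, TEACHER_HYPER, opts, rng_seed=seed + 3)
    iopts = InferenceOptions(lr_r=0.1, lr_rh=0.05, max_iters=150, tol=1e-6)
    traj = filter_sequence(test, student, TEACHER_HYPER, iopts)
    pred = traj.r_bar @ student.U.T
    resid = test[:, 2:] - pred[:, 2:]
    r2 = 1.0 - float(np.sum(resid**2) / np.sum((test[:, 2:] - test[:, 2:].mean()) ** 2))
    return {"r2": r2, "loss_initial": hist["loss"][0], "loss_final": hist["loss"][-1]}


# ---------------------------------------------------------------------------
# Sprite study: training, timescales, factorization, flash-lag, recall
# ---------------------------------------------------------------------------


def sprite_corpus(seed: int, n_sequences: int = 2000, frame_size: int = 18, T: int = 10):
    """Moving-sprite corpus: uniform start positions, fixed speed, straight
    bounces at the frame boundary (the emulated handwritten-digit
    protocol)."""

    spec = SpriteDatasetSpec(
        n_sequences=n_sequences, frame_size=frame_size, T=T, speed=1, rng_seed=seed,
    )
    return make_moving_sprites(spec)


def train_sprite_coder(
    seed: int,
    n_sequences: int = 2000,
    epochs: int = 8,
    n_components: int = 64,
    n_higher: int = 16,
) -> DynamicPredictiveCoder:
    """Fit the flagship two-level network on a sprite corpus."""

    data = sprite_corpus(seed * 1000 + 17, n_sequences)
    coder = DynamicPredictiveCoder(
        n_components=n_components, n_higher=n_higher, epochs=epochs, random_state=seed
    )
    coder.fit(data)
    return coder


def sprite_study(
    coder: DynamicPredictiveCoder,
    seed: int,
    n_test: int = 160,
    k_max: int = 6,
    noise_T: int = 20,
    n_noise: int = 100,
    n_folds: int = 5,
) -> dict:
    """Timescale and factorization metrics from one pass over held-out data.

    Timescales: population autocorrelation of each level's responses to
    held-out sprites and to white noise, with the fitted exponential tau.
    Factorization: SVM decoding of motion direction and sprite identity
    from each level's responses, averaged over the early window t = 1..3 —
    after the first-step adaptation but (for uniform start positions)
    before most bounces, so direction information can only come from the
    inferred dynamics, not from where the sprite happens to sit.
    """

    test = sprite_corpus(seed * 1000 + 901, n_test)
    traj = coder.filter(test)
    out = {}
    for name, series in (("r", traj.r_hat), ("rh", traj.r_h_hat)):
        ac = autocorrelation(series, k_max)
        out[f"tau_{name}_sprites"] = fit_exponential_decay(ac.rho).tau
    M = coder.shape_.M
    noise = make_white_noise(T=noise_T, M=M, rng_seed=seed * 1000 + 902, n_sequences=n_noise)
    trajn = coder.filter(noise.frames)
    for name, series in (("r", trajn.r_hat), ("rh", trajn.r_h_hat)):
        ac = autocorrelation(series, k_max)
        out[f"tau_{name}_noise"] = fit_exponential_decay(ac.rho).tau

    feat_r = traj.r_hat[:, 1:4].mean(axis=1)
    feat_rh = traj.r_h_hat[:, 1:4].mean(axis=1)
    y_dir = test.labels["direction"]
    y_spr = test.labels["sprite_id"]
    for key, X, y in (
        ("direction_rh", feat_rh, y_dir),
        ("direction_r", feat_r, y_dir),
        ("sprite_r", feat_r, y_spr),
        ("sprite_rh", feat_rh, y_spr),
    ):
        res = crossval_decode(X, y, n_folds=n_folds, random_state=seed)
        out[f"acc_{key}"] = res.mean_accuracy
        out[f"chance_{key}"] = res.chance
    return out


def timescale_experiment(coder: DynamicPredictiveCoder, seed: int, **kwargs) -> dict:
    """Fitted autocorrelation timescales of both levels (see sprite_study)."""

    out = sprite_study(coder, seed, **kwargs)
    return {k: v for k, v in out.items() if k.startswith("tau_")}


def factorization_experiment(coder: DynamicPredictiveCoder, seed: int, **kwargs) -> dict:
    """Direction/identity decoding from each level (see sprite_study)."""

    out = sprite_study(coder, seed, **kwargs)
    return {k: v for k, v in out.items() if k.startswith(("acc_", "chance_"))}


def flashlag_experiment(
    coder: DynamicPredictiveCoder,
    seed: int,
    n_sequences: int = 48,
    sweep_fractions: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0),
) -> dict:
    """Flash-lag displacement structure and the latency (postdiction) sweep."""

    spec = SpriteDatasetSpec(
        n_sequences=n_sequences * 3, frame_size=18, T=10, speed=1,
        directions=("left", "right"), rng_seed=seed * 1000 + 33,
    )
    data = make_moving_sprites(spec)
    selected = select_consistent_sequences(data, length=5)
    selected.frames = selected.frames[:n_sequences]
    selected.labels = {k: v[:n_sequences] for k, v in selected.labels.items()}

    opts = coder.infer_opts()
    table = flash_lag_table(coder.params_, coder.hyper_, selected, opts)
    out = {"n_sequences": len(selected.frames)}
    for traj_cond in ("with_initial", "without_initial"):
        sub = table[table.trajectory == traj_cond]
        for case in ("continuous", "stopped", "reversed", "terminated"):
            vals = sub[sub.motion_case == case]["displacement"].dropna()
            out[f"disp_{case}_{traj_cond}"] = float(vals.mean())

    sweep = latency_sweep(coder.params_, coder.hyper_, selected, sweep_fractions, opts)
    piv = sweep.pivot(index="sequence", columns="fraction", values="displacement")
    out["disp_early_10pct"] = float(piv[0.1].mean())
    out["disp_late_90pct"] = float(piv[0.9].mean())
    diffs = piv.values[:, 1:] - piv.values[:, :-1]
    out["frac_monotone_sweep"] = float(np.mean(np.all(diffs <= 0.35, axis=1)))
    return out


def _frame_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-frame Pearson correlation of two (T, M) sequences."""

    cs = []
    for t in range(a.shape[0]):
        x, y = a[t], b[t]
        if x.std() < 1e-12 or y.std() < 1e-12:
            cs.append(0.0)
        else:
            cs.append(float(np.corrcoef(x, y)[0, 1]))
    return float(np.mean(cs))


MEMORY_SPRITES = ("blob", "ring", "cross")


def memory_sprite_corpus(seed: int, n_sequences: int = 1000):
    """Small-sprite corpus for the episodic-memory study.

    Five-pixel sprites leave room for a trajectory longer than the object,
    so a recalled sequence sweeps activity across distinct receptive
    fields (the dot-traversal geometry of the conditioning experiments)."""

    spec = SpriteDatasetSpec(
        n_sequences=n_sequences, frame_size=18, T=10, speed=1,
        sprite_size=5, sprite_bank=MEMORY_SPRITES, rng_seed=seed,
    )
    return make_moving_sprites(spec)


def train_memory_coder(seed: int, n_sequences: int = 1500, epochs: int = 10) -> DynamicPredictiveCoder:
    """Network for the memory study: fixed retinotopic front end.

    A learned undercomplete dictionary goes global (every RF centroid at
    the frame center), which makes RF-distance analyses meaningless; the
    memory study therefore fixes the spatial filters to a retinotopic
    blob dictionary and learns only the dynamics on top.
    """

    data = memory_sprite_corpus(seed * 1000 + 19, n_sequences)
    coder = DynamicPredictiveCoder(
        n_components=100, n_higher=16, filters="retinotopic",
        sigma_r2=0.1, lambda_sparse=0.03, epochs=epochs, random_state=seed,
    )
    coder.fit(data)
    return coder


def recall_experiment(
    coder: DynamicPredictiveCoder,
    seed: int,
    n_episodes: int = 3,
    max_lag: int = 4,
    xcorr_T: int = 10,
    path_band: float = 3.0,
) -> dict:
    """Conditioning on sprite episodes and cue-triggered recall.

    Each episode is a five-step constant-motion window bound into its own
    fresh associative memory (five Hebbian repetitions, frozen network).
    Reports, averaged over episodes: the mean frame correlation of
    rollouts cued by the start, middle and end frames, and the "After
    minus Before" cross-correlation peak-lag slope against RF distance.
    Following the conditioning experiments this analysis emulates, only
    neurons whose RFs lie along the sprite's path (within ``path_band``
    pixels of the trajectory row) are analyzed, and the rollout is
    extended to ``xcorr_T`` steps so integer-lag estimates have support.
    """

    from dataclasses import replace as _replace

    import dpcnet.memory as memory_ops

    spec = SpriteDatasetSpec(
        n_sequences=8 * n_episodes, frame_size=18, T=10, speed=1,
        sprite_size=5, sprite_bank=MEMORY_SPRITES, directions=("left", "right"),
        rng_seed=seed * 1000 + 71,
    )
    windows = select_consistent_sequences(make_moving_sprites(spec), 5)
    H, W = 18, 18
    pos, _ = memory_ops.rf_positions(coder.params_.U, (H, W))

    corrs = {"start": [], "middle": [], "end": []}
    slopes = []
    for ep in range(min(n_episodes, len(windows.frames))):
        episode = windows.frames[ep]
        mem = EpisodicMemory(coder, random_state=seed + ep)
        before = mem._fresh()
        mem.fit(episode[None])
        for name, idx in (("start", 0), ("middle", 2), ("end", 4)):
            frames, _ = mem.rollout(episode[idx], T=5)
            corrs[name].append(_frame_correlation(frames, episode))

        r0_cue = coder.encode_first_frame(episode[0])
        _, rh_before = memory_ops.recall_from_cue(before, r0_cue, coder.shape_.N)
        _, rh_after = mem.recall(episode[0])
        _, resp_b = memory_ops.rollout_recall(coder.params_, r0_cue, rh_before, xcorr_T)
        _, resp_a = memory_ops.rollout_recall(coder.params_, r0_cue, rh_after, xcorr_T)

        imgs = episode.reshape(5, H, W)
        ys, xs = np.arange(H), np.arange(W)
        path_y = np.mean([(im.sum(axis=1) * ys).sum() / im.sum() for im in imgs])
        x0 = (imgs[0].sum(axis=0) * xs).sum() / imgs[0].sum()
        x1 = (imgs[-1].sum(axis=0) * xs).sum() / imgs[-1].sum()
        sign = 1.0 if x1 >= x0 else -1.0
        keep = (np.abs(pos[:, 1] - path_y) < path_band) & (
            resp_a.std(axis=0) > 0.05 * resp_a.std(axis=0).max()
        )
        idxs = np.where(keep)[0]
        if len(idxs) < 4:
            continue
        cc_b = rf_distance_crosscorr(
            resp_b[:, idxs], coder.params_.U[:, idxs], (H, W),
            max_lag=max_lag, direction_sign=sign,
        )
        cc_a = rf_distance_crosscorr(
            resp_a[:, idxs], coder.params_.U[:, idxs], (H, W),
            max_lag=max_lag, direction_sign=sign,
        )
        common = set(zip(cc_b.pairs["i"], cc_b.pairs["j"])) & set(
            zip(cc_a.pairs["i"], cc_a.pairs["j"])
        )
        if len(common) < 2:
            continue

        def subset(cc):
            mask = np.array([k in common for k in zip(cc.pairs["i"], cc.pairs["j"])])
            return _replace(cc, pairs=cc.pairs[mask].reset_index(drop=True), xcorr=cc.xcorr[mask])

        slopes.append(crosscorr_difference_slope(subset(cc_b), subset(cc_a)))

    out = {f"recall_corr_{k}": float(np.mean(v)) for k, v in corrs.items()}
    out["xcorr_diff_slope"] = float(np.mean(slopes)) if slopes else float("nan")
    return out


# ---------------------------------------------------------------------------
# Three-level study
# ---------------------------------------------------------------------------


def _bounce_spec(seed: int, n: int, rule: str, frame_size: int = 16, T: int = 24):
    # small sprites at speed 1: within-segment dynamics stay learnable at
    # desk scale, trajectories are longer than the object, and T = 24
    # guarantees at least two bounces per sequence
    return SpriteDatasetSpec(
        n_sequences=n, frame_size=frame_size, T=T, speed=1, bounce_rule=rule,
        sprite_size=5, sprite_bank=MEMORY_SPRITES, rng_seed=seed,
    )


def train_bounce_model(
    seed: int,
    n_per_type: int = 100,
    epochs: int = 5,
    n_components: int = 81,
    n_higher: int = 16,
    n3: int = 12,
) -> tuple[ThreeLevelDynamicPredictiveCoder, dict]:
    """Fit the three-level model on a mixed straight/clockwise corpus.

    The base uses the fixed retinotopic front end (spatially resolved
    prediction errors) with the memory study's hyperparameters.
    """

    straight = make_bouncing_dataset(_bounce_spec(seed * 1000 + 1, n_per_type, "straight"))
    clockwise = make_bouncing_dataset(_bounce_spec(seed * 1000 + 2, n_per_type, "clockwise"))
    frames = np.concatenate([straight.frames, clockwise.frames])
    y = np.concatenate([np.zeros(n_per_type, int), np.ones(n_per_type, int)])

    base = DynamicPredictiveCoder(
        n_components=n_components, n_higher=n_higher, filters="retinotopic",
        sigma_r2=0.1, lambda_sparse=0.03, epochs=epochs, random_state=seed,
    )
    base.fit(frames)
    model = ThreeLevelDynamicPredictiveCoder(base=base, n3=n3, random_state=seed)
    model.fit(frames, y)
    return model, {"n_per_type": n_per_type}


def threelevel_experiment(
    model: ThreeLevelDynamicPredictiveCoder,
    seed: int,
    n_test_per_type: int = 50,
    n_folds: int = 5,
    k_max: int = 8,
) -> dict:
    """Decoding, gate-detection and timescale metrics of the trained
    three-level network on held-out bouncing sequences."""

    straight = make_bouncing_dataset(_bounce_spec(seed * 1000 + 51, n_test_per_type, "straight"))
    clockwise = make_bouncing_dataset(_bounce_spec(seed * 1000 + 52, n_test_per_type, "clockwise"))
    frames = np.concatenate([straight.frames, clockwise.frames])
    y_type = np.concatenate([np.zeros(n_test_per_type, int), np.ones(n_test_per_type, int)])
    y_dir = np.concatenate(
        [straight.labels["direction"], clockwise.labels["direction"]]
    )
    bounce_mask = np.concatenate(
        [straight.labels["bounce_mask"], clockwise.labels["bounce_mask"]]
    )
    traj = model.filter3(frames)
    B, T = traj.flags.shape

    # bounce type read out from the final-step modulation weights (the
    # current dynamics after all bounces); direction from the pre-bounce
    # window mean, where the regimes are indistinguishable by construction
    first_bounce = np.array(
        [np.argmax(bounce_mask[b]) if bounce_mask[b].any() else T for b in range(B)]
    )
    feat_final = {"w1": traj.w1[:, -1], "w2": traj.w2[:, -1]}
    feat_pre = {"w1": np.zeros((B, traj.w1.shape[2])), "w2": np.zeros((B, traj.w2.shape[2]))}
    for b in range(B):
        fb = max(int(first_bounce[b]), 2)
        feat_pre["w1"][b] = traj.w1[b, 1:fb].mean(axis=0)
        feat_pre["w2"][b] = traj.w2[b, 1:fb].mean(axis=0)

    out = {}
    for key, X, y in (
        ("bounce_w2", feat_final["w2"], y_type),
        ("bounce_w1", feat_final["w1"], y_type),
        ("direction_w1", feat_pre["w1"], y_dir),
        ("direction_w2", feat_pre["w2"], y_dir),
    ):
        res = crossval_decode(X, y, n_folds=n_folds, random_state=seed)
        out[f"acc_{key}"] = res.mean_accuracy
        out[f"chance_{key}"] = res.chance

    # gate flags vs labeled bounce frames, past the adaptation transient
    t0 = model.transient_steps
    pred = traj.flags[:, t0:]
    true = bounce_mask[:, t0:]
    tp = float(np.sum(pred & true))
    out["flag_precision"] = tp / max(float(pred.sum()), 1.0)
    out["flag_recall"] = tp / max(float(true.sum()), 1.0)

    for name, series in (("r1", traj.r1), ("r2", traj.r2), ("r3", traj.r3)):
        ac = autocorrelation(series, k_max)
        out[f"tau_{name}"] = fit_exponential_decay(ac.rho).tau
    return out
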