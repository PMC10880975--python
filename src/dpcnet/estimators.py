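"""Scikit-learn style estimators wrapping the DPC machinery.

``DynamicPredictiveCoder`` is an unsupervised transformer: ``fit`` learns
the spatial dictionary, transition bank and hypernetwork from a corpus of
image sequences; ``transform`` returns per-sequence latent summaries;
``predict`` returns one-step-ahead frame predictions and ``score`` their
R^2.  ``ThreeLevelDynamicPredictiveCoder`` stacks the gated third level on
top (supervised only in that pretraining needs the bouncing-regime label
of each sequence).  ``EpisodicMemory`` binds episodes filtered by a fitted
coder into an associative memory and supports cue-triggered recall.
``SequenceWhitener`` is a stateless preprocessing transformer.

All estimators follow sklearn conventions (``get_params``/``set_params``,
fitted attributes with trailing underscores, ``check_is_fitted``) and
compose with sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import memory as memory_ops
from .datasets import SequenceBatch
from .inference import InferenceOptions, filter_sequence, infer_first_step
from .model import DPCParameters, Hyperparameters, ModelShape
from .preprocess import whiten_sequences
from .threelevel import (
    ThreeLevelParameters,
    estimate_threshold,
    infer_three_level,
    pretrain_second_level,
    random_level2,
    train_three_level,
)
from .training import TrainingOptions, train_two_level

__all__ = [
    "SequenceWhitener",
    "DynamicPredictiveCoder",
    "ThreeLevelDynamicPredictiveCoder",
    "EpisodicMemory",
]


def _as_frames(X) -> tuple[np.ndarray, tuple[int, int] | None]:
    """Coerce input to (B, T, M) plus an optional frame shape."""

    if isinstance(X, SequenceBatch):
        return X.frames, X.frame_shape
    A = np.asarray(X, dtype=float)
    if A.ndim == 4:
        B, T, H, W = A.shape
        return A.reshape(B, T, H * W), (H, W)
    if A.ndim == 3:
        return A, None
    raise ValueError("expected SequenceBatch, (B, T, M) or (B, T, H, W)")


class SequenceWhitener(TransformerMixin, BaseEstimator):
    """Spatial (frequency-domain) and temporal whitening of sequences."""

    def __init__(self, f0_fraction: float = 0.8, temporal: bool = True, alpha: float = 0.8):
        self.f0_fraction = f0_fraction
        self.temporal = temporal
        self.alpha = alpha

    def fit(self, X, y=None):
        frames, shape = _as_frames(X)
        if shape is None:
            side = int(round(np.sqrt(frames.shape[2])))
            if side * side != frames.shape[2]:
                raise ValueError("cannot infer frame shape from flattened frames")
            shape = (side, side)
        self.frame_shape_ = shape
        self.n_features_in_ = frames.shape[2]
        return self

    def transform(self, X):
        check_is_fitted(self, "frame_shape_")
        if isinstance(X, SequenceBatch):
            return whiten_sequences(
                X, f0_fraction=self.f0_fraction, temporal=self.temporal, alpha=self.alpha
            )
        frames, shape = _as_frames(X)
        out = whiten_sequences(
            frames,
            frame_shape=shape or self.frame_shape_,
            f0_fraction=self.f0_fraction,
            temporal=self.temporal,
            alpha=self.alpha,
        )
        return out.reshape(np.asarray(X).shape)


class DynamicPredictiveCoder(TransformerMixin, BaseEstimator):
    """Two-level dynamic predictive coding network.

    Parameters mirror the generative model: ``n_components`` first-level
    neurons (columns of ``U``), ``n_higher`` second-level neurons,
    ``n_transitions`` transition matrices mixed by the hypernetwork with
    hidden widths ``hidden``.  ``sigma2``/``sigma_r2`` weight the image and
    temporal prediction errors; ``lambda_sparse``/``lambda_h`` are the
    sparsity and higher-level prior penalties.  Training minimizes the
    filtering loss over ``epochs`` passes with Adam at rate ``lr``.
    """

    def __init__(
        self,
        n_components: int = 64,
        n_higher: int = 16,
        n_transitions: int = 5,
        hidden: tuple[int, ...] = (64,),
        sigma2: float = 0.5,
        sigma_r2: float = 0.25,
        lambda_sparse: float = 0.02,
        lambda_h: float = 0.005,
        epochs: int = 12,
        batch_size: int = 64,
        lr: float = 0.005,
        train_max_iters: int = 25,
        analysis_max_iters: int = 100,
        infer_lr_r: float = 0.1,
        infer_lr_rh: float = 0.05,
        filters: str = "learned",
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.n_higher = n_higher
        self.n_transitions = n_transitions
        self.hidden = hidden
        self.sigma2 = sigma2
        self.sigma_r2 = sigma_r2
        self.lambda_sparse = lambda_sparse
        self.lambda_h = lambda_h
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.train_max_iters = train_max_iters
        self.analysis_max_iters = analysis_max_iters
        self.infer_lr_r = infer_lr_r
        self.infer_lr_rh = infer_lr_rh
        self.filters = filters
        self.random_state = random_state

    # -- option bundles -------------------------------------------------
    @property
    def hyper_(self) -> Hyperparameters:
        return Hyperparameters(
            sigma2=self.sigma2,
            sigma_r2=self.sigma_r2,
            lambda_sparse=self.lambda_sparse,
            lambda_h=self.lambda_h,
        )

    def _train_opts(self) -> TrainingOptions:
        return TrainingOptions(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            learn_U=self.filters == "learned",
            infer=InferenceOptions(
                lr_r=self.infer_lr_r,
                lr_rh=self.infer_lr_rh,
                max_iters=self.train_max_iters,
                tol=1e-4,
            ),
        )

    def infer_opts(self, max_iters: int | None = None) -> InferenceOptions:
        return InferenceOptions(
            lr_r=self.infer_lr_r,
            lr_rh=self.infer_lr_rh,
            max_iters=self.analysis_max_iters if max_iters is None else max_iters,
            tol=1e-5,
        )

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y=None):
        frames, frame_shape = _as_frames(X)
        shape = ModelShape(
            M=frames.shape[2],
            N=self.n_components,
            N_h=self.n_higher,
            K=self.n_transitions,
            hypernet_layers=tuple(self.hidden),
        )
        seed = 0 if self.random_state is None else self.random_state
        init = None
        if self.filters == "retinotopic":
            if frame_shape is None:
                side = int(round(np.sqrt(shape.M)))
                if side * side != shape.M:
                    raise ValueError("retinotopic filters need a 2-D frame shape")
                frame_shape = (side, side)
            from .model import random_parameters, retinotopic_dictionary

            init = random_parameters(shape, np.random.default_rng(seed))
            init.U = retinotopic_dictionary(frame_shape, shape.N, seed)
        elif self.filters != "learned":
            raise ValueError("filters must be 'learned' or 'retinotopic'")
        params, history = train_two_level(
            frames, shape, self.hyper_, self._train_opts(), rng_seed=seed, init=init
        )
        self.params_ = params
        self.U_ = params.U
        self.V_ = params.V
        self.theta_ = params.theta
        self.shape_ = shape
        self.frame_shape_ = frame_shape
        self.history_ = history
        self.n_features_in_ = frames.shape[2]
        return self

    def filter(self, X, max_iters: int | None = None, rh_init=None):
        """Full MAP filtering of sequences; returns a Trajectory."""

        check_is_fitted(self, "params_")
        frames, _ = _as_frames(X)
        return filter_sequence(frames, self.params_, self.hyper_, self.infer_opts(max_iters), rh_init)

    def transform(self, X):
        """Per-sequence summary features: time-mean of r and r_h."""

        traj = self.filter(X)
        return np.concatenate(
            [traj.r_hat.mean(axis=1), traj.r_h_hat.mean(axis=1)], axis=1
        )

    def predict(self, X):
        """One-step-ahead frame predictions ``U r_bar_t`` (first step zero)."""

        traj = self.filter(X)
        return traj.r_bar @ self.params_.U.T

    def score(self, X, y=None) -> float:
        """R^2 of one-step predictions against the shown frames (t >= 2)."""

        frames, _ = _as_frames(X)
        pred = self.predict(X)
        resid = frames[:, 2:] - pred[:, 2:]
        ss_res = float(np.sum(resid**2))
        mu = frames[:, 2:].mean()
        ss_tot = float(np.sum((frames[:, 2:] - mu) ** 2))
        return 1.0 - ss_res / ss_tot

    def encode_first_frame(self, frame: np.ndarray, max_iters: int | None = None):
        """Sparse code of a single frame (content vector ``r_0``)."""

        check_is_fitted(self, "params_")
        r0, _ = infer_first_step(frame, self.params_, self.hyper_, self.infer_opts(max_iters))
        return r0


class ThreeLevelDynamicPredictiveCoder(BaseEstimator):
    """Three-level DPC with threshold-gated second-level transitions.

    ``fit(X, y)`` expects the bouncing-regime label of each sequence in
    ``y`` (0 = straight, 1 = clockwise), needed only for pretraining the
    two second-level transition matrices.  A prefit two-level coder may be
    supplied; otherwise one is trained on the corpus first.
    """

    def __init__(
        self,
        base: DynamicPredictiveCoder | None = None,
        n3: int = 12,
        hidden2: tuple[int, ...] = (16,),
        threshold_quantile: float = 0.75,
        sigma_r2_level2: float = 1.0,
        lambda_3: float = 0.01,
        pretrain_epochs: int = 3,
        epochs: int = 6,
        lr: float = 0.01,
        transient_steps: int = 3,
        random_state: int | None = 0,
    ):
        self.base = base
        self.n3 = n3
        self.hidden2 = hidden2
        self.threshold_quantile = threshold_quantile
        self.sigma_r2_level2 = sigma_r2_level2
        self.lambda_3 = lambda_3
        self.pretrain_epochs = pretrain_epochs
        self.epochs = epochs
        self.lr = lr
        self.transient_steps = transient_steps
        self.random_state = random_state

    def fit(self, X, y):
        frames, frame_shape = _as_frames(X)
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must contain regime labels 0 (straight) and 1 (clockwise)")
        seed = 0 if self.random_state is None else self.random_state

        if self.base is not None:
            check_is_fitted(self.base, "params_")
            coder = self.base
        else:
            coder = DynamicPredictiveCoder(random_state=seed)
            coder.fit(X)
        self.coder_ = coder
        base_params = coder.params_
        hyper = coder.hyper_

        # threshold from first-level prediction errors past the transient
        traj = filter_sequence(frames, base_params, hyper, coder.infer_opts(coder.train_max_iters))
        errs = traj.pred_err[:, self.transient_steps :]
        self.rho_ = estimate_threshold(errs, self.threshold_quantile)

        opts = TrainingOptions(
            epochs=self.pretrain_epochs,
            batch_size=64,
            lr=self.lr,
            infer=InferenceOptions(
                lr_r=coder.infer_lr_r, lr_rh=coder.infer_lr_rh,
                max_iters=coder.train_max_iters, tol=1e-4,
            ),
        )
        V2 = pretrain_second_level(
            frames[y == 0], frames[y == 1], base_params, self.rho_, hyper, opts,
            rng_seed=seed, sigma_r2_level2=self.sigma_r2_level2,
        )
        _, theta2 = random_level2(
            base_params.shape.N_h, self.n3, K2=2, hidden=tuple(self.hidden2), rng=seed,
        )
        params3 = ThreeLevelParameters(
            base=base_params, V2=V2, theta2=theta2, rho=self.rho_,
            sigma_r2_level2=self.sigma_r2_level2,
        )
        opts_joint = TrainingOptions(
            epochs=self.epochs, batch_size=64, lr=self.lr, infer=opts.infer
        )
        self.params3_, self.history_ = train_three_level(
            frames, params3, hyper, opts_joint, rng_seed=seed, lambda_3=self.lambda_3
        )
        self.frame_shape_ = frame_shape
        return self

    def filter3(self, X, max_iters: int | None = None):
        """Three-level MAP filtering; returns a ThreeLevelTrajectory."""

        check_is_fitted(self, "params3_")
        frames, _ = _as_frames(X)
        return infer_three_level(
            frames, self.params3_, self.coder_.hyper_,
            self.coder_.infer_opts(max_iters), lambda_3=self.lambda_3,
        )


class EpisodicMemory(BaseEstimator):
    """Associative memory over a fitted coder's (r_0, r_h) bindings."""

    def __init__(
        self,
        coder: DynamicPredictiveCoder,
        P: int | None = None,
        lambda_m: float = 0.1,
        eta_G: float = 0.05,
        n_reps: int = 5,
        init_scale: float = 1e-3,
        random_state: int | None = 0,
    ):
        self.coder = coder
        self.P = P
        self.lambda_m = lambda_m
        self.eta_G = eta_G
        self.n_reps = n_reps
        self.init_scale = init_scale
        self.random_state = random_state

    def _fresh(self):
        check_is_fitted(self.coder, "params_")
        n_bound = self.coder.shape_.N + self.coder.shape_.N_h
        seed = 0 if self.random_state is None else self.random_state
        return memory_ops.init_memory(
            n_bound, self.P, seed, scale=self.init_scale,
            lambda_m=self.lambda_m, eta_G=self.eta_G,
        )

    def fit(self, X, y=None):
        """Condition on episodes: filter each sequence, bind (r_0, r_h)."""

        frames, _ = _as_frames(X)
        mem = self._fresh()
        self.episodes_ = []
        for b in range(frames.shape[0]):
            traj = self.coder.filter(frames[b][None])
            r0 = traj.r_hat[0, 0]
            rh = traj.r_h_hat[0, -1]
            mem, errors = memory_ops.memory_store(mem, r0, rh, n_reps=self.n_reps)
            self.episodes_.append({"r0": r0, "rh": rh, "store_errors": errors})
        self.memory_ = mem
        return self

    def recall(self, cue_frame: np.ndarray):
        """Recall the dynamics vector from a single cue frame."""

        check_is_fitted(self, "memory_")
        r0_cue = self.coder.encode_first_frame(cue_frame)
        _, rh = memory_ops.recall_from_cue(self.memory_, r0_cue, self.coder.shape_.N)
        return r0_cue, rh

    def rollout(self, cue_frame: np.ndarray, T: int = 5):
        """Cue-triggered sequence recall through the frozen coder."""

        r0_cue, rh = self.recall(cue_frame)
        return memory_ops.rollout_recall(self.coder.params_, r0_cue, rh, T)
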