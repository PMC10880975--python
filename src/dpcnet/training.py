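"""Parameter learning for the two-level DPC model.

Training alternates (i) MAP inference of the latent states of a minibatch
with the current parameters (the E-like step, done by
:func:`dpcnet.inference.filter_sequence`) and (ii) a gradient update of the
parameters ``U``, ``{V_k}`` and the hypernetwork weights on the filtering
loss summed across time and averaged across sequences, evaluated at the
MAP latents (the M-like step).  Columns of ``U`` are renormalized to unit
L2 norm after every update to remove the scale degeneracy of sparse coding
(the latent L1 penalty would otherwise be driven to zero by growing the
filters).

The parameter gradients are analytic and finite-difference checked; the
default optimizer is Adam (plain SGD available).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import SequenceBatch
from .inference import InferenceOptions, filter_sequence, Trajectory
from .model import (
    DPCParameters,
    Hyperparameters,
    ModelShape,
    first_step_loss_grads,
    random_parameters,
    step_loss_grads,
)

__all__ = ["TrainingOptions", "Adam", "sequence_param_grads", "train_two_level"]


@dataclass(frozen=True)
class TrainingOptions:
    """Settings for two-level training.

    ``infer`` holds the inner-loop options used during training; they are
    deliberately coarser (fewer iterations, looser tolerance) than the
    defaults used for analysis-time inference.
    """

    epochs: int = 100
    batch_size: int = 64
    lr: float = 0.005
    optimizer: str = "adam"
    renorm_U: bool = True
    learn_U: bool = True
    shuffle: bool = True
    infer: InferenceOptions = field(
        default_factory=lambda: InferenceOptions(lr_r=0.1, lr_rh=0.05, max_iters=30, tol=1e-4)
    )

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.lr < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


class Adam:
    """Minimal Adam optimizer over a list of arrays."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, values: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(x) for x in values]
            self.v = [np.zeros_like(x) for x in values]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for x, g, m, v in zip(values, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            x -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def _flatten_params(params: DPCParameters) -> list[np.ndarray]:
    out = [params.U, params.V]
    for W, b in params.theta:
        out.extend([W, b])
    return out


def sequence_param_grads(
    frames: np.ndarray,
    traj: Trajectory,
    params: DPCParameters,
    hyper: Hyperparameters,
) -> tuple[float, dict]:
    """Gradient of the filtering loss w.r.t. the parameters.

    The loss is the per-step MAP loss summed across time and averaged
    across the batch, with the latent estimates in ``traj`` held fixed.
    The temporal prediction at each step is recomputed from the stored
    per-step higher-level estimate, so the hypernetwork and transition
    matrices receive gradients through it.  Returns ``(loss, grads)`` with
    grads keyed by ``U``, ``V``, ``theta``.
    """

    X = np.asarray(frames, dtype=float)
    if X.ndim == 2:
        X = X[None]
    B, T, _ = X.shape
    g_U = np.zeros_like(params.U)
    g_V = np.zeros_like(params.V)
    g_theta = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params.theta]

    fs = first_step_loss_grads(X[:, 0], traj.r_hat[:, 0], params, hyper)
    total = float(np.sum(fs["loss"]))
    g_U += fs["U"]

    for t in range(1, T):
        gs = step_loss_grads(
            X[:, t], traj.r_hat[:, t], traj.r_h_hat[:, t], traj.r_hat[:, t - 1], params, hyper
        )
        total += float(np.sum(gs["loss"]))
        g_U += gs["U"]
        g_V += gs["V"]
        for i, (dW, db) in enumerate(gs["theta"]):
            g_theta[i] = (g_theta[i][0] + dW, g_theta[i][1] + db)

    scale = 1.0 / B
    grads = {
        "U": g_U * scale,
        "V": g_V * scale,
        "theta": [(dW * scale, db * scale) for dW, db in g_theta],
    }
    return total * scale, grads


def train_two_level(
    dataset,
    shape: ModelShape,
    hyper: Hyperparameters,
    opts: TrainingOptions = TrainingOptions(),
    rng_seed: int | np.random.Generator = 0,
    *,
    init: DPCParameters | None = None,
) -> tuple[DPCParameters, dict]:
    """Learn ``U``, ``{V_k}`` and the hypernetwork from a sequence corpus.

    ``dataset`` is a :class:`~dpcnet.datasets.SequenceBatch` or an array
    ``(B, T, M)`` of equal-length sequences.  Returns the learned
    parameters and a history dict with the mean per-sequence loss per
    epoch.
    """

    X = dataset.frames if isinstance(dataset, SequenceBatch) else np.asarray(dataset, dtype=float)
    if X.ndim != 3 or X.shape[0] == 0:
        raise ValueError("dataset must be a nonempty (B, T, M) batch")
    rng = np.random.default_rng(rng_seed)
    params = init.copy() if init is not None else random_parameters(shape, rng)

    flat = _flatten_params(params)
    optimizer = Adam(opts.lr) if opts.optimizer == "adam" else None
    n = X.shape[0]
    history = {"loss": []}

    for _ in range(opts.epochs):
        order = rng.permutation(n) if opts.shuffle else np.arange(n)
        epoch_losses = []
        for start in range(0, n, opts.batch_size):
            idx = order[start : start + opts.batch_size]
            batch = X[idx]
            traj = filter_sequence(batch, params, hyper, opts.infer)
            loss, grads = sequence_param_grads(batch, traj, params, hyper)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training loss diverged (non-finite) at learning rate {opts.lr}"
                )
            epoch_losses.append(loss)
            flat_grads = [grads["U"] if opts.learn_U else np.zeros_like(grads["U"]), grads["V"]]
            for dW, db in grads["theta"]:
                flat_grads.extend([dW, db])
            if opts.lr > 0:
                if optimizer is not None:
                    optimizer.step(flat, flat_grads)
                else:
                    for x, g in zip(flat, flat_grads):
                        x -= opts.lr * g
                if opts.renorm_U and opts.learn_U:
                    norms = np.linalg.norm(params.U, axis=0, keepdims=True)
                    params.U /= np.maximum(norms, 1e-12)
        history["loss"].append(float(np.mean(epoch_losses)))

    return params, history
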