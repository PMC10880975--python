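"""Three-level DPC: threshold-gated second-level transitions.

The two-level model assumes one dynamics vector explains a whole sequence,
so it cannot represent *changes* of dynamics (e.g. a bounce).  The
three-level extension lets the second-level state transition — but only
when the first-level prediction error exceeds a threshold ``rho``
(the analogue of a terminal state in a hierarchical HMM).  The transition
is linear, ``r2_bar_t = V2 r2_{t-1}``, with ``V2`` mixed from a small bank
by weights ``w2 = H2(r3)`` generated by the third-level state through a
second hypernetwork.  The per-step loss is the two-level loss with the
Gaussian prior penalty moved up one level (to ``r3``) and the second-level
transition term gated by the binary flag ``b_t``::

    L = ||I - U r1||^2/(2 s2) + ||r1 - r1_bar||^2/(2 sr2)
        + b_t ||r2 - V2 r2_{t-1}||^2/(2 sr2_2) + lam ||r1||_1  [+ lam3 ||r3||^2]

When ``b_t = 0`` the second level holds its previous state as its
prediction (identity carry) and ``r3`` receives no gradient, so the third
level is only corrected at dynamics changes — which is what makes its
timescale the longest in the hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import SequenceBatch
from .inference import InferenceOptions, infer_first_step, _check_finite
from .model import (
    DPCParameters,
    Hyperparameters,
    hypernet_forward,
    hypernet_backward,
)
from .training import Adam, TrainingOptions

__all__ = [
    "ThreeLevelParameters",
    "ThreeLevelTrajectory",
    "random_level2",
    "estimate_threshold",
    "masked_level2_loss",
    "infer_three_level",
    "pretrain_second_level",
    "train_three_level",
]


@dataclass
class ThreeLevelParameters:
    """Parameters of the three-level model.

    base : the two-level parameters (levels 1-2).
    V2 : ``(K2, N_h, N_h)`` second-level transition matrices (K2 = 2 for
        the two bouncing regimes).
    theta2 : second hypernetwork mapping ``r3`` (length ``N3``) to ``w2``.
    rho : first-level prediction-error threshold gating second-level
        transitions.
    sigma_r2_level2 : variance of the second-level transition noise.
    """

    base: DPCParameters
    V2: np.ndarray
    theta2: list[tuple[np.ndarray, np.ndarray]]
    rho: float
    sigma_r2_level2: float = 1.0

    def __post_init__(self) -> None:
        self.V2 = np.asarray(self.V2, dtype=float)
        if self.V2.ndim != 3 or self.V2.shape[1] != self.V2.shape[2]:
            raise ValueError("V2 must be (K2, N_h, N_h)")
        if self.V2.shape[1] != self.base.shape.N_h:
            raise ValueError("V2 dimension must match the second-level width")
        if not self.rho > 0:
            raise ValueError("rho must be positive")
        self.theta2 = [(np.asarray(W, float), np.asarray(b, float)) for W, b in self.theta2]
        if self.theta2[-1][0].shape[0] != self.V2.shape[0]:
            raise ValueError("second hypernetwork output must equal K2")

    @property
    def K2(self) -> int:
        return self.V2.shape[0]

    @property
    def N3(self) -> int:
        return self.theta2[0][0].shape[1]


@dataclass
class ThreeLevelTrajectory:
    """Extended trajectory with per-step states of all three levels."""

    r1: np.ndarray
    r2: np.ndarray
    r3: np.ndarray
    w1: np.ndarray
    w2: np.ndarray
    flags: np.ndarray  # (B, T) boolean b_t
    pred_err: np.ndarray
    r2_bar: np.ndarray
    final_loss: np.ndarray


def random_level2(
    N_h: int,
    N3: int,
    K2: int = 2,
    hidden: tuple[int, ...] = (16,),
    rng: np.random.Generator | int = 0,
    *,
    v2_scale: float = 0.5,
    theta_scale: float = 0.5,
) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
    """Random initialization of the second-level bank and hypernetwork."""

    rng = np.random.default_rng(rng)
    V2 = v2_scale * rng.standard_normal((K2, N_h, N_h)) / np.sqrt(N_h)
    widths = [N3, *hidden, K2]
    theta2 = []
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        theta2.append(
            (theta_scale * rng.standard_normal((n_out, n_in)) / np.sqrt(n_in), np.zeros(n_out))
        )
    return V2, theta2


def estimate_threshold(first_level_errors: np.ndarray, quantile: float = 0.75) -> float:
    """Empirical quantile (linear interpolation) of first-level errors."""

    e = np.asarray(first_level_errors, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("need a nonempty error sample")
    return float(np.quantile(e, quantile))


def masked_level2_loss(
    I_t: np.ndarray,
    r1: np.ndarray,
    r1_bar: np.ndarray,
    r2: np.ndarray,
    r2_bar: np.ndarray,
    b_t: float | np.ndarray,
    params: ThreeLevelParameters,
    hyper: Hyperparameters,
    *,
    r3: np.ndarray | None = None,
    lambda_3: float = 0.0,
) -> np.ndarray:
    """Gated per-step loss of the three-level model (predictions given)."""

    U = params.base.U
    recon = np.sum((np.atleast_2d(I_t) - np.atleast_2d(r1) @ U.T) ** 2, axis=-1) / (2 * hyper.sigma2)
    t1 = np.sum((np.asarray(r1) - np.asarray(r1_bar)) ** 2, axis=-1) / (2 * hyper.sigma_r2)
    sparse = hyper.lambda_sparse * np.sum(np.abs(np.asarray(r1)), axis=-1)
    t2 = np.asarray(b_t, dtype=float) * np.sum(
        (np.asarray(r2) - np.asarray(r2_bar)) ** 2, axis=-1
    ) / (2 * params.sigma_r2_level2)
    out = recon + t1 + sparse + t2
    if r3 is not None and lambda_3 > 0:
        out = out + lambda_3 * np.sum(np.asarray(r3) ** 2, axis=-1)
    out = np.asarray(out)
    return out if out.size > 1 else float(out.ravel()[0])


def _infer_step3(
    I_t,
    r1_prev,
    r2_in,
    r3_in,
    params: ThreeLevelParameters,
    hyper: Hyperparameters,
    opts: InferenceOptions,
    *,
    fixed_w2: np.ndarray | None = None,
    lambda_h2: float = 0.0,
    lambda_3: float | None = None,
    force_b: str = "auto",
    lr_r3: float | None = None,
):
    """One gated filtering step over (r1, r2, r3); mirrors the two-level
    joint update so that with all gates off it reproduces it exactly."""

    base = params.base
    U, V1, theta1 = base.U, base.V, base.theta
    lam = hyper.lambda_sparse
    lam3 = hyper.lambda_h if lambda_3 is None else lambda_3
    lr3 = opts.lr_rh if lr_r3 is None else lr_r3
    s2r2 = params.sigma_r2_level2
    B = I_t.shape[0]

    P1 = np.einsum("kij,bj->kbi", V1, r1_prev)
    Q = np.einsum("kij,bj->kbi", params.V2, r2_in)

    # pre-correction first-level prediction and gate
    w1_0, _ = hypernet_forward(r2_in, theta1, return_cache=True)
    w1_0 = np.atleast_2d(w1_0)
    pre1_0 = np.einsum("bk,kbi->bi", w1_0, P1)
    r1_bar_init = np.maximum(pre1_0, 0.0)
    pred_err = np.linalg.norm(I_t - r1_bar_init @ U.T, axis=1)
    if force_b == "auto":
        b = (pred_err > params.rho).astype(float)
    elif force_b == "zero":
        b = np.zeros(B)
    elif force_b == "one":
        b = np.ones(B)
    else:
        raise ValueError("force_b must be 'auto', 'zero' or 'one'")

    use_h2 = fixed_w2 is None

    def level2_parts(r3_):
        if use_h2:
            w2_, cache2_ = hypernet_forward(r3_, params.theta2, return_cache=True)
            w2_ = np.atleast_2d(w2_)
        else:
            w2_, cache2_ = fixed_w2, None
        pre2_ = np.einsum("bk,kbi->bi", w2_, Q)
        return w2_, cache2_, pre2_

    def level1_parts(r2_):
        w1_, cache1_ = hypernet_forward(r2_, theta1, return_cache=True)
        w1_ = np.atleast_2d(w1_)
        pre1_ = np.einsum("bk,kbi->bi", w1_, P1)
        return w1_, cache1_, pre1_, np.maximum(pre1_, 0.0)

    def loss_of(r1_, rbar1_, r2_, pre2_, r3_):
        resid = I_t - r1_ @ U.T
        out = (
            np.sum(resid * resid, axis=1) / (2 * hyper.sigma2)
            + np.sum((r1_ - rbar1_) ** 2, axis=1) / (2 * hyper.sigma_r2)
            + lam * np.sum(np.abs(r1_), axis=1)
            + lambda_h2 * np.sum(r2_ * r2_, axis=1)
        )
        out = out + b * (np.sum((r2_ - pre2_) ** 2, axis=1) / (2 * s2r2))
        out = out + lam3 * np.sum(r3_ * r3_, axis=1)
        return out, resid

    r2 = r2_in.copy()
    r3 = r3_in.copy()
    w1, cache1, pre1, rbar1 = level1_parts(r2)
    w2, cache2, pre2 = level2_parts(r3)
    r1 = rbar1.copy()
    cur, resid_cur = loss_of(r1, rbar1, r2, pre2, r3)
    r2_bar = np.where(b[:, None] > 0, pre2, r2_in)

    def soft(x, thr):
        return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)

    for _ in range(opts.max_iters):
        resid_T1 = (r1 - rbar1) / hyper.sigma_r2
        g_r1 = -(resid_cur @ U) / hyper.sigma2 + resid_T1
        if not opts.prox_l1:
            g_r1 = g_r1 + lam * np.sign(r1)
        g_pre1 = -resid_T1 * (pre1 > 0)
        dw1 = np.einsum("bi,kbi->bk", g_pre1, P1)
        g_r2_net, _ = hypernet_backward(theta1, cache1, dw1)
        resid_T2 = b[:, None] * (r2 - pre2) / s2r2
        g_r2 = np.atleast_2d(g_r2_net) + resid_T2 + 2.0 * lambda_h2 * r2
        if use_h2:
            dw2 = np.einsum("bi,kbi->bk", -resid_T2, Q)
            g_r3_net, _ = hypernet_backward(params.theta2, cache2, dw2)
            g_r3 = np.atleast_2d(g_r3_net) + 2.0 * lam3 * r3
        else:
            g_r3 = np.zeros_like(r3)

        scale = np.ones(B)
        accepted = None
        for _ in range(opts.max_halvings + 1):
            sr = (scale * opts.lr_r)[:, None]
            sh = (scale * opts.lr_rh)[:, None]
            s3 = (scale * lr3)[:, None]
            cand_r1 = soft(r1 - sr * g_r1, sr * lam) if opts.prox_l1 else r1 - sr * g_r1
            cand_r2 = r2 - sh * g_r2
            cand_r3 = r3 - s3 * g_r3
            w1_c, cache1_c, pre1_c, rbar1_c = level1_parts(cand_r2)
            w2_c, cache2_c, pre2_c = level2_parts(cand_r3)
            new, resid_new = loss_of(cand_r1, rbar1_c, cand_r2, pre2_c, cand_r3)
            _check_finite(new, opts.lr_r, "three-level step")
            bad = new > cur + 1e-12
            if not opts.backtracking or not np.any(bad):
                accepted = (cand_r1, cand_r2, cand_r3, w1_c, cache1_c, pre1_c, rbar1_c,
                            w2_c, cache2_c, pre2_c, new, resid_new)
                break
            scale[bad] *= 0.5
        if accepted is None:
            cand_r1[bad] = r1[bad]
            cand_r2[bad] = r2[bad]
            cand_r3[bad] = r3[bad]
            w1_c, cache1_c, pre1_c, rbar1_c = level1_parts(cand_r2)
            w2_c, cache2_c, pre2_c = level2_parts(cand_r3)
            new, resid_new = loss_of(cand_r1, rbar1_c, cand_r2, pre2_c, cand_r3)
            accepted = (cand_r1, cand_r2, cand_r3, w1_c, cache1_c, pre1_c, rbar1_c,
                        w2_c, cache2_c, pre2_c, new, resid_new)
        (cand_r1, cand_r2, cand_r3, w1, cache1, pre1, rbar1, w2, cache2, pre2, new,
         resid_cur) = accepted
        delta = float(
            max(
                np.max(np.abs(cand_r1 - r1)),
                np.max(np.abs(cand_r2 - r2)),
                np.max(np.abs(cand_r3 - r3)),
            )
        )
        r1, r2, r3, cur = cand_r1, cand_r2, cand_r3, new
        if delta < opts.tol:
            break

    return {
        "r1": r1,
        "r2": r2,
        "r3": r3,
        "r1_bar": r1_bar_init,
        "r2_bar": r2_bar,
        "b": b.astype(bool),
        "pred_err": pred_err,
        "loss": cur,
        "w2": w2,
    }


def infer_three_level(
    frames: np.ndarray,
    params: ThreeLevelParameters,
    hyper: Hyperparameters,
    opts: InferenceOptions = InferenceOptions(),
    *,
    fixed_w2: np.ndarray | None = None,
    lambda_h2: float = 0.0,
    lambda_3: float | None = None,
    force_b: str = "auto",
) -> ThreeLevelTrajectory:
    """Filter sequences with the gated three-level model.

    ``r2`` and ``r3`` start at zero and are carried across steps; ``r3`` is
    only corrected at steps whose first-level prediction error exceeds
    ``rho`` (``force_b`` can pin the gate for diagnostics).  With
    ``force_b='zero'`` and ``lambda_h2`` set to the two-level prior weight,
    the trajectory of (r1, r2) reproduces the two-level filter exactly.
    """

    X = np.asarray(frames, dtype=float)
    if X.ndim == 2:
        X = X[None]
    B, T, M = X.shape
    base = params.base
    N, N_h = base.shape.N, base.shape.N_h
    N3 = params.N3
    K2 = params.K2

    r1 = np.zeros((B, T, N))
    r2 = np.zeros((B, T, N_h))
    r3 = np.zeros((B, T, N3))
    w1 = np.zeros((B, T, base.shape.K))
    w2 = np.zeros((B, T, K2))
    flags = np.zeros((B, T), dtype=bool)
    pred_err = np.zeros((B, T))
    r2_bar = np.zeros((B, T, N_h))
    final_loss = np.zeros((B, T))

    r0, diag0 = infer_first_step(X[:, 0], base, hyper, opts)
    r1[:, 0] = r0
    w1[:, 0] = np.atleast_2d(hypernet_forward(np.zeros((B, N_h)), base.theta))
    if fixed_w2 is None:
        w2[:, 0] = np.atleast_2d(hypernet_forward(np.zeros((B, N3)), params.theta2))
    else:
        w2[:, 0] = fixed_w2
    pred_err[:, 0] = np.linalg.norm(X[:, 0], axis=1)
    final_loss[:, 0] = diag0["loss"][-1]

    cur_r2 = np.zeros((B, N_h))
    cur_r3 = np.zeros((B, N3))
    for t in range(1, T):
        out = _infer_step3(
            X[:, t], r1[:, t - 1], cur_r2, cur_r3, params, hyper, opts,
            fixed_w2=fixed_w2, lambda_h2=lambda_h2, lambda_3=lambda_3, force_b=force_b,
        )
        cur_r2, cur_r3 = out["r2"], out["r3"]
        r1[:, t] = out["r1"]
        r2[:, t] = cur_r2
        r3[:, t] = cur_r3
        w1[:, t] = np.atleast_2d(hypernet_forward(cur_r2, base.theta))
        w2[:, t] = out["w2"] if fixed_w2 is None else fixed_w2
        flags[:, t] = out["b"]
        pred_err[:, t] = out["pred_err"]
        r2_bar[:, t] = out["r2_bar"]
        final_loss[:, t] = out["loss"]

    return ThreeLevelTrajectory(
        r1=r1, r2=r2, r3=r3, w1=w1, w2=w2, flags=flags, pred_err=pred_err,
        r2_bar=r2_bar, final_loss=final_loss,
    )


def pretrain_second_level(
    straight_dataset,
    clockwise_dataset,
    base: DPCParameters,
    rho: float,
    hyper: Hyperparameters,
    opts: TrainingOptions = TrainingOptions(epochs=10),
    rng_seed: int | np.random.Generator = 0,
    *,
    sigma_r2_level2: float = 1.0,
) -> np.ndarray:
    """Learn one second-level transition matrix per bouncing regime.

    For each regime separately, a single ``V2`` is learned by gradient
    descent on the gated loss (inference with that fixed matrix, then a
    parameter step), giving the bank ``{V2_straight, V2_clockwise}`` used
    by the full three-level model.  Raises if the data produce no flagged
    transitions (then there is nothing for the second level to learn).
    """

    rng = np.random.default_rng(rng_seed)
    N_h = base.shape.N_h
    out = np.zeros((2, N_h, N_h))
    for d_i, data in enumerate((straight_dataset, clockwise_dataset)):
        X = data.frames if isinstance(data, SequenceBatch) else np.asarray(data, float)
        V2 = np.eye(N_h) + 0.01 * rng.standard_normal((N_h, N_h))
        tmp = ThreeLevelParameters(
            base=base, V2=V2[None], theta2=[(np.zeros((1, 1)), np.zeros(1))], rho=rho,
            sigma_r2_level2=sigma_r2_level2,
        )
        optimizer = Adam(opts.lr) if opts.optimizer == "adam" else None
        n = X.shape[0]
        total_flags = 0
        for _ in range(opts.epochs):
            order = rng.permutation(n) if opts.shuffle else np.arange(n)
            for start in range(0, n, opts.batch_size):
                batch = X[order[start : start + opts.batch_size]]
                B = batch.shape[0]
                fixed_w2 = np.ones((B, 1))
                traj = infer_three_level(batch, tmp, hyper, opts.infer, fixed_w2=fixed_w2)
                total_flags += int(traj.flags.sum())
                g = np.zeros_like(V2)
                for t in range(1, batch.shape[1]):
                    bmask = traj.flags[:, t].astype(float)[:, None]
                    pre2 = traj.r2[:, t - 1] @ V2.T
                    resid = bmask * (pre2 - traj.r2[:, t]) / sigma_r2_level2
                    g += resid.T @ traj.r2[:, t - 1]
                g /= B
                if opts.lr > 0:
                    if optimizer is not None:
                        optimizer.step([V2], [g])
                    else:
                        V2 -= opts.lr * g
                tmp.V2 = V2[None]
        if total_flags == 0:
            raise ValueError(
                "no first-level errors exceeded rho; use longer sequences or a lower threshold"
            )
        out[d_i] = V2
    return out


def train_three_level(
    dataset,
    params: ThreeLevelParameters,
    hyper: Hyperparameters,
    opts: TrainingOptions = TrainingOptions(epochs=10),
    rng_seed: int | np.random.Generator = 0,
    *,
    learn_V2: bool = False,
    lambda_3: float | None = None,
) -> tuple[ThreeLevelParameters, dict]:
    """Learn the third-level hypernetwork on a mixed-regime corpus.

    Alternates three-level inference with gradient updates of ``theta2``
    (and optionally fine-tuning of ``V2``) on the gated loss summed over
    time and averaged over sequences.  Returns updated parameters and the
    epoch loss history.
    """

    X = dataset.frames if isinstance(dataset, SequenceBatch) else np.asarray(dataset, float)
    if X.ndim != 3 or X.shape[0] == 0:
        raise ValueError("dataset must be a nonempty (B, T, M) batch")
    rng = np.random.default_rng(rng_seed)
    params = ThreeLevelParameters(
        base=params.base, V2=params.V2.copy(),
        theta2=[(W.copy(), b.copy()) for W, b in params.theta2],
        rho=params.rho, sigma_r2_level2=params.sigma_r2_level2,
    )
    flat = [W for W, _ in params.theta2] + [b for _, b in params.theta2]
    if learn_V2:
        flat.append(params.V2)
    optimizer = Adam(opts.lr) if opts.optimizer == "adam" else None
    n = X.shape[0]
    history = {"loss": []}
    for _ in range(opts.epochs):
        order = rng.permutation(n) if opts.shuffle else np.arange(n)
        epoch_losses = []
        for start in range(0, n, opts.batch_size):
            batch = X[order[start : start + opts.batch_size]]
            B, T, _ = batch.shape
            traj = infer_three_level(batch, params, hyper, opts.infer, lambda_3=lambda_3)
            g_theta2 = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params.theta2]
            g_V2 = np.zeros_like(params.V2)
            total = float(traj.final_loss.sum())
            for t in range(1, T):
                bmask = traj.flags[:, t].astype(float)[:, None]
                w2_t, cache2 = hypernet_forward(traj.r3[:, t], params.theta2, return_cache=True)
                w2_t = np.atleast_2d(w2_t)
                Q = np.einsum("kij,bj->kbi", params.V2, traj.r2[:, t - 1])
                pre2 = np.einsum("bk,kbi->bi", w2_t, Q)
                g_pre2 = bmask * (pre2 - traj.r2[:, t]) / params.sigma_r2_level2
                dw2 = np.einsum("bi,kbi->bk", g_pre2, Q)
                _, dtheta2 = hypernet_backward(params.theta2, cache2, dw2)
                for i, (dW, db) in enumerate(dtheta2):
                    g_theta2[i] = (g_theta2[i][0] + dW, g_theta2[i][1] + db)
                if learn_V2:
                    g_V2 += np.einsum("bk,bi,bj->kij", w2_t, g_pre2, traj.r2[:, t - 1])
            epoch_losses.append(total / B)
            flat_grads = [dW / B for dW, _ in g_theta2] + [db / B for _, db in g_theta2]
            if learn_V2:
                flat_grads.append(g_V2 / B)
            if opts.lr > 0:
                if optimizer is not None:
                    optimizer.step(flat, flat_grads)
                else:
                    for x, g in zip(flat, flat_grads):
                        x -= opts.lr * g
        history["loss"].append(float(np.mean(epoch_losses)))
    return params, history
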