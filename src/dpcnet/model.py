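"""Core generative model for dynamic predictive coding (DPC).

A two-level hierarchical generative model of image sequences.  At the lower
level, each frame ``I_t`` (a vectorized grayscale image of ``M`` pixels) is
generated from a sparse latent state ``r_t`` of dimension ``N`` through a
dictionary of spatial filters ``U`` (columns are filters)::

    I_t | r_t  ~  N(U r_t, sigma2 * I)

The temporal dynamics of ``r_t`` are modulated from above: a higher-level
state ``r_h`` of dimension ``N_h`` is mapped by a small hypernetwork
``H_theta`` to ``K`` modulation weights ``w``, which mix a bank of learned
transition matrices ``{V_k}`` into the effective dynamics::

    w   = H_theta(r_h)
    V   = sum_k w_k V_k
    r_t | r_{t-1}, r_h  ~  N(ReLU(V r_{t-1}), sigma_r2 * I)

The prior on ``r_h`` is standard normal.  The hypernetwork is a multi-layer
perceptron with tanh hidden nonlinearities and a linear output of size ``K``
(a single affine layer when no hidden widths are given).

All functions accept either single state vectors or batches (leading batch
axis); gradients are computed analytically and are verified against central
finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelShape",
    "Hyperparameters",
    "DPCParameters",
    "LatentState",
    "random_parameters",
    "hypernet_forward",
    "hypernet_backward",
    "mix_transitions",
    "transition_mean",
    "decode_image",
    "step_loss",
    "first_step_loss",
    "step_loss_joint",
    "step_loss_grads",
    "first_step_loss_grads",
    "sample_generative",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelShape:
    """Dimensions of a two-level DPC model.

    Parameters
    ----------
    M : int
        Input dimensionality (pixels per vectorized frame).
    N : int
        First-level latent dimensionality.
    N_h : int
        Second-level latent dimensionality.
    K : int
        Number of first-level transition matrices (default 5).
    hypernet_layers : tuple of int
        Hidden-layer widths of the hypernetwork ``H_theta``.  Empty tuple
        means a single affine map from ``r_h`` to ``w``.
    """

    M: int
    N: int = 128
    N_h: int = 32
    K: int = 5
    hypernet_layers: tuple[int, ...] = (64,)

    def __post_init__(self) -> None:
        for name in ("M", "N", "N_h", "K"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if any(h <= 0 for h in self.hypernet_layers):
            raise ValueError("hypernet hidden widths must be positive")
        object.__setattr__(self, "hypernet_layers", tuple(int(h) for h in self.hypernet_layers))


@dataclass(frozen=True)
class Hyperparameters:
    """Noise variances and prior penalties of the DPC loss.

    sigma2 : observation-noise variance of the image likelihood.
    sigma_r2 : transition-noise variance of the first-level dynamics.
    lambda_sparse : L1 (sparsity) penalty weight on ``r_t``.
    lambda_h : squared-norm (Gaussian prior) penalty weight on ``r_h``.
    """

    sigma2: float = 1.0
    sigma_r2: float = 1.0
    lambda_sparse: float = 0.0
    lambda_h: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")
        if not self.sigma_r2 > 0:
            raise ValueError(f"sigma_r2 must be > 0, got {self.sigma_r2}")
        if self.lambda_sparse < 0 or self.lambda_h < 0:
            raise ValueError("penalty weights must be nonnegative")


@dataclass
class DPCParameters:
    """Trainable parameters of a two-level DPC model.

    U : (M, N) spatial filter dictionary; columns are filters.
    V : (K, N, N) stack of transition matrices.
    theta : list of (W, b) affine layers of the hypernetwork, with tanh
        between layers and a linear output of size K.
    """

    U: np.ndarray
    V: np.ndarray
    theta: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.theta = [(np.asarray(W, dtype=float), np.asarray(b, dtype=float)) for W, b in self.theta]
        if self.U.ndim != 2:
            raise ValueError("U must be 2-D (M, N)")
        if self.V.ndim != 3 or self.V.shape[1] != self.V.shape[2]:
            raise ValueError("V must be a (K, N, N) stack of square matrices")
        if self.V.shape[1] != self.U.shape[1]:
            raise ValueError("V and U latent dimensions disagree")
        for W, b in self.theta:
            if W.ndim != 2 or b.ndim != 1 or W.shape[0] != b.shape[0]:
                raise ValueError("each hypernet layer must be (W: (out, in), b: (out,))")
        if self.theta[-1][0].shape[0] != self.V.shape[0]:
            raise ValueError("hypernet output dimension must equal K")
        arrays = [self.U, self.V] + [a for layer in self.theta for a in layer]
        if not all(np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("parameters contain non-finite entries")

    @property
    def shape(self) -> ModelShape:
        return ModelShape(
            M=self.U.shape[0],
            N=self.U.shape[1],
            N_h=self.theta[0][0].shape[1],
            K=self.V.shape[0],
            hypernet_layers=tuple(W.shape[0] for W, _ in self.theta[:-1]),
        )

    def copy(self) -> "DPCParameters":
        return DPCParameters(
            U=self.U.copy(),
            V=self.V.copy(),
            theta=[(W.copy(), b.copy()) for W, b in self.theta],
        )


@dataclass
class LatentState:
    """Point estimate of the latent variables at one time step."""

    r: np.ndarray
    r_h: np.ndarray
    w: np.ndarray


def retinotopic_dictionary(
    frame_shape: tuple[int, int],
    n_units: int,
    rng: np.random.Generator | int = 0,
    *,
    sigma: float = 2.0,
    margin: float = 2.0,
) -> np.ndarray:
    """Fixed localized spatial dictionary: Gaussian blobs tiling the frame.

    Columns are unit-norm Gaussian envelopes centered on a jittered grid —
    an innate retinotopic front end.  With the dictionary held fixed,
    training learns only the dynamics on top of a position-preserving
    code, which keeps receptive-field locations meaningful (a learned
    undercomplete dictionary goes global, putting every RF centroid at
    the frame center).
    """

    H, W = frame_shape
    rng = np.random.default_rng(rng)
    side = int(np.ceil(np.sqrt(n_units)))
    cy = np.linspace(margin, H - 1 - margin, side)
    cx = np.linspace(margin, W - 1 - margin, side)
    centers = [(y, x) for y in cy for x in cx][:n_units]
    ys, xs = np.mgrid[0:H, 0:W]
    U = np.zeros((H * W, n_units))
    for i, (y0, x0) in enumerate(centers):
        y0 = y0 + rng.uniform(-0.5, 0.5)
        x0 = x0 + rng.uniform(-0.5, 0.5)
        env = np.exp(-((ys - y0) ** 2 + (xs - x0) ** 2) / (2 * sigma**2))
        U[:, i] = env.ravel()
    U /= np.linalg.norm(U, axis=0, keepdims=True)
    return U


def random_parameters(
    shape: ModelShape,
    rng: np.random.Generator,
    *,
    u_scale: float | None = None,
    v_spectral_radius: float = 0.9,
    v_identity_bias: float = 0.0,
    theta_scale: float = 0.5,
) -> DPCParameters:
    """Draw random parameters with unit-norm filters and stable dynamics.

    Columns of ``U`` are normalized to unit L2 norm.  Each transition matrix
    is ``v_identity_bias * I`` plus a random matrix rescaled to spectral
    radius ``v_spectral_radius``; a nonzero identity bias yields temporally
    smooth dynamics whose activity does not die under the transition ReLU
    (the realistic regime for natural motion, and the construction used for
    "teacher" models in the self-consistency protocols).
    """

    U = rng.standard_normal((shape.M, shape.N))
    if u_scale is not None:
        U *= u_scale
    U /= np.linalg.norm(U, axis=0, keepdims=True)
    V = rng.standard_normal((shape.K, shape.N, shape.N)) / np.sqrt(shape.N)
    for k in range(shape.K):
        radius = np.max(np.abs(np.linalg.eigvals(V[k])))
        if radius > 0:
            V[k] *= v_spectral_radius / radius
        V[k] += v_identity_bias * np.eye(shape.N)
    widths = [shape.N_h, *shape.hypernet_layers, shape.K]
    theta = []
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        W = rng.standard_normal((n_out, n_in)) * theta_scale / np.sqrt(n_in)
        b = np.zeros(n_out)
        theta.append((W, b))
    # Bias the output layer so that H(0) mixes the mean transition matrix:
    # at the zero-initialized r_h the modulated dynamics would otherwise be
    # the zero matrix and the transition ReLU would block all gradients.
    theta[-1] = (theta[-1][0], np.full(shape.K, 1.0 / shape.K))
    return DPCParameters(U=U, V=V, theta=theta)


# ---------------------------------------------------------------------------
# Forward (top-down) computations
# ---------------------------------------------------------------------------


def _atleast_2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def hypernet_forward(
    r_h: np.ndarray,
    theta: Sequence[tuple[np.ndarray, np.ndarray]],
    *,
    return_cache: bool = False,
):
    """Map the higher-level state to modulation weights, ``w = H_theta(r_h)``.

    ``r_h`` may be a single vector ``(N_h,)`` or a batch ``(B, N_h)``.
    With ``return_cache=True`` also returns the per-layer activations needed
    by :func:`hypernet_backward`.
    """

    x, squeeze = _atleast_2d(r_h)
    if x.shape[1] != theta[0][0].shape[1]:
        raise ValueError(
            f"r_h has length {x.shape[1]} but hypernet expects {theta[0][0].shape[1]}"
        )
    cache = [x]
    n_layers = len(theta)
    for i, (W, b) in enumerate(theta):
        x = x @ W.T + b
        if i < n_layers - 1:
            x = np.tanh(x)
        cache.append(x)
    out = x[0] if squeeze else x
    if return_cache:
        return out, cache
    return out


def hypernet_backward(
    theta: Sequence[tuple[np.ndarray, np.ndarray]],
    cache: list[np.ndarray],
    dw: np.ndarray,
) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
    """Backpropagate ``dL/dw`` through the hypernetwork.

    Returns ``(dL/dr_h, dL/dtheta)`` with the parameter gradients summed
    over the batch axis.
    """

    g, squeeze = _atleast_2d(dw)
    dtheta: list[tuple[np.ndarray, np.ndarray]] = [None] * len(theta)  # type: ignore[list-item]
    n_layers = len(theta)
    for i in range(n_layers - 1, -1, -1):
        W, _ = theta[i]
        if i < n_layers - 1:
            # cache[i + 1] holds tanh(pre-activation) of hidden layer i
            g = g * (1.0 - cache[i + 1] ** 2)
        x_in = cache[i] if i == 0 else cache[i]
        dW = g.T @ x_in
        db = g.sum(axis=0)
        dtheta[i] = (dW, db)
        g = g @ W
    drh = g[0] if squeeze else g
    return drh, dtheta


def mix_transitions(w: np.ndarray, V_set: np.ndarray) -> np.ndarray:
    """Linearly combine transition matrices: ``V = sum_k w_k V_k``.

    ``w`` may be ``(K,)`` or ``(B, K)``; the result is ``(N, N)`` or
    ``(B, N, N)`` accordingly.
    """

    w = np.asarray(w, dtype=float)
    V_set = np.asarray(V_set, dtype=float)
    if w.shape[-1] != V_set.shape[0]:
        raise ValueError(f"w has {w.shape[-1]} entries but there are {V_set.shape[0]} matrices")
    return np.einsum("...k,kij->...ij", w, V_set)


def transition_mean(r_prev: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Mean of the next first-level state: ``ReLU(V r_prev)``."""

    r_prev = np.asarray(r_prev, dtype=float)
    V = np.asarray(V, dtype=float)
    if V.shape[-1] != r_prev.shape[-1]:
        raise ValueError(f"V acts on dimension {V.shape[-1]} but r_prev has {r_prev.shape[-1]}")
    pre = np.einsum("...ij,...j->...i", V, r_prev)
    return np.maximum(pre, 0.0)


def decode_image(r: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Top-down image prediction ``U r`` (no clipping)."""

    r = np.asarray(r, dtype=float)
    U = np.asarray(U, dtype=float)
    if U.shape[1] != r.shape[-1]:
        raise ValueError(f"U has {U.shape[1]} columns but r has length {r.shape[-1]}")
    return r @ U.T


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def _sq(x: np.ndarray) -> np.ndarray:
    return np.sum(x * x, axis=-1)


def step_loss(
    I_t: np.ndarray,
    r_t: np.ndarray,
    r_bar_t: np.ndarray,
    r_h: np.ndarray,
    params: DPCParameters,
    hyper: Hyperparameters,
) -> np.ndarray:
    """Per-step MAP loss with the temporal prediction ``r_bar_t`` held fixed.

    L = ||I - U r||^2 / (2 sigma2) + ||r - r_bar||^2 / (2 sigma_r2)
        + lambda ||r||_1 + lambda_h ||r_h||^2

    Inputs may be batched on a leading axis; the result is then a vector.
    """

    I_t = np.asarray(I_t, dtype=float)
    r_t = np.asarray(r_t, dtype=float)
    recon = _sq(I_t - decode_image(r_t, params.U)) / (2.0 * hyper.sigma2)
    temporal = _sq(r_t - np.asarray(r_bar_t, dtype=float)) / (2.0 * hyper.sigma_r2)
    sparse = hyper.lambda_sparse * np.sum(np.abs(r_t), axis=-1)
    prior_h = hyper.lambda_h * _sq(np.asarray(r_h, dtype=float))
    return recon + temporal + sparse + prior_h


def first_step_loss(
    I_0: np.ndarray,
    r_0: np.ndarray,
    params: DPCParameters,
    hyper: Hyperparameters,
) -> np.ndarray:
    """Reduced loss for the first step (no temporal or higher-level terms)."""

    I_0 = np.asarray(I_0, dtype=float)
    r_0 = np.asarray(r_0, dtype=float)
    recon = _sq(I_0 - decode_image(r_0, params.U)) / (2.0 * hyper.sigma2)
    return recon + hyper.lambda_sparse * np.sum(np.abs(r_0), axis=-1)


def step_loss_joint(
    I_t: np.ndarray,
    r_t: np.ndarray,
    r_h: np.ndarray,
    r_prev: np.ndarray,
    params: DPCParameters,
    hyper: Hyperparameters,
) -> np.ndarray:
    """Step loss with ``r_bar`` recomputed from ``(r_h, r_prev)``."""

    w = hypernet_forward(r_h, params.theta)
    r_bar = transition_mean(r_prev, mix_transitions(w, params.V))
    return step_loss(I_t, r_t, r_bar, r_h, params, hyper)


def step_loss_grads(
    I_t: np.ndarray,
    r_t: np.ndarray,
    r_h: np.ndarray,
    r_prev: np.ndarray,
    params: DPCParameters,
    hyper: Hyperparameters,
) -> dict:
    """Analytic gradients of the joint per-step loss.

    Returns a dict with the scalar (or batched) ``loss`` and gradients with
    respect to ``r`` (smooth part plus L1 subgradient, with sign(0) = 0),
    ``r_h``, ``U``, ``V`` and ``theta``.  Parameter gradients are summed
    over the batch.  The ReLU subgradient at 0 is taken to be 0.
    """

    I2, _ = _atleast_2d(I_t)
    r2, squeeze = _atleast_2d(r_t)
    rh2, _ = _atleast_2d(r_h)
    rp2, _ = _atleast_2d(r_prev)

    w, cache = hypernet_forward(rh2, params.theta, return_cache=True)
    # P[k, b, :] = V_k r_prev_b ; shared by forward mean and all gradients
    P = np.einsum("kij,bj->kbi", params.V, rp2)
    pre = np.einsum("bk,kbi->bi", w, P)
    r_bar = np.maximum(pre, 0.0)

    resid_I = r2 @ params.U.T - I2                    # (B, M)
    resid_T = (r2 - r_bar) / hyper.sigma_r2           # (B, N)

    loss = (
        _sq(I2 - r2 @ params.U.T) / (2.0 * hyper.sigma2)
        + _sq(r2 - r_bar) / (2.0 * hyper.sigma_r2)
        + hyper.lambda_sparse * np.sum(np.abs(r2), axis=-1)
        + hyper.lambda_h * _sq(rh2)
    )

    g_r = resid_I @ params.U / hyper.sigma2 + resid_T + hyper.lambda_sparse * np.sign(r2)

    g_pre = -resid_T * (pre > 0)                      # dL/d(pre-activation)
    dw = np.einsum("bi,kbi->bk", g_pre, P)
    g_rh_net, dtheta = hypernet_backward(params.theta, cache, dw)
    g_rh = np.atleast_2d(g_rh_net) + 2.0 * hyper.lambda_h * rh2

    g_U = resid_I.T @ r2 / hyper.sigma2
    g_V = np.einsum("bk,bi,bj->kij", w, g_pre, rp2)

    if squeeze:
        return {
            "loss": float(loss[0]),
            "r": g_r[0],
            "r_h": g_rh[0],
            "U": g_U,
            "V": g_V,
            "theta": dtheta,
            "r_bar": r_bar[0],
            "w": w[0],
        }
    return {"loss": loss, "r": g_r, "r_h": g_rh, "U": g_U, "V": g_V, "theta": dtheta,
            "r_bar": r_bar, "w": w}


def first_step_loss_grads(
    I_0: np.ndarray,
    r_0: np.ndarray,
    params: DPCParameters,
    hyper: Hyperparameters,
) -> dict:
    """Analytic gradients of the first-step loss w.r.t. ``r_0`` and ``U``."""

    I2, _ = _atleast_2d(I_0)
    r2, squeeze = _atleast_2d(r_0)
    resid = r2 @ params.U.T - I2
    loss = _sq(-resid) / (2.0 * hyper.sigma2) + hyper.lambda_sparse * np.sum(np.abs(r2), axis=-1)
    g_r = resid @ params.U / hyper.sigma2 + hyper.lambda_sparse * np.sign(r2)
    g_U = resid.T @ r2 / hyper.sigma2
    if squeeze:
        return {"loss": float(loss[0]), "r": g_r[0], "U": g_U}
    return {"loss": loss, "r": g_r, "U": g_U}


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def sample_generative(
    params: DPCParameters,
    T: int,
    rng: np.random.Generator | int,
    *,
    n_sequences: int = 1,
    sigma2: float = 0.0,
    sigma_r2: float = 0.0,
    r0_scale: float = 1.0,
) -> tuple[np.ndarray, dict]:
    """Sample image sequences from the generative model.

    ``r_h ~ N(0, I)``; ``r_0 ~ N(0, r0_scale^2 I)`` (the generative prior on
    the initial state is not pinned down by the inference loss, which only
    places an L1 penalty on ``r_0``; an isotropic Gaussian is the default).
    Then ``r_{t+1} = ReLU(V r_t) + m`` with ``m ~ N(0, sigma_r2 I)`` and
    ``I_t = U r_t + n`` with ``n ~ N(0, sigma2 I)``.

    Returns ``(frames, latents)`` where ``frames`` has shape
    ``(n_sequences, T, M)`` and ``latents`` contains the true ``r`` series
    ``(n_sequences, T, N)``, the per-sequence ``r_h`` and mixing weights
    ``w``.
    """

    if T < 1:
        raise ValueError("T must be >= 1")
    if sigma2 < 0 or sigma_r2 < 0:
        raise ValueError("noise variances must be nonnegative")
    rng = np.random.default_rng(rng)
    shape = params.shape
    B = n_sequences
    r_h = rng.standard_normal((B, shape.N_h))
    w = hypernet_forward(r_h, params.theta)
    V = mix_transitions(w, params.V)                  # (B, N, N)
    r = np.empty((B, T, shape.N))
    r[:, 0] = r0_scale * rng.standard_normal((B, shape.N))
    for t in range(1, T):
        mean = transition_mean(r[:, t - 1], V)
        noise = rng.standard_normal((B, shape.N)) * np.sqrt(sigma_r2) if sigma_r2 > 0 else 0.0
        r[:, t] = mean + noise
    frames = np.einsum("mn,btn->btm", params.U, r)
    if sigma2 > 0:
        frames = frames + rng.standard_normal(frames.shape) * np.sqrt(sigma2)
    return frames, {"r": r, "r_h": r_h, "w": w}
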