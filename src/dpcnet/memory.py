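"""Associative memory for episodic storage and cue-triggered recall.

The two-level DPC network factorizes a sequence into a content vector
``r_0`` (what is shown at the first step) and a dynamics vector ``r_h``
(how it moves).  An associative memory — playing the role of the
hippocampus — binds the concatenated pair ``s = [r_0; r_h]`` to a memory
vector ``m`` through a synaptic matrix ``G`` under the predictive-coding
objective::

    L_memory(G, m) = ||s - G m||^2 + lambda_m ||m||^2

Storage (conditioning) alternates inference of ``m`` with Hebbian updates
of ``G`` driven by presynaptic activity and postsynaptic prediction error;
the DPC network itself is frozen.  Recall from a visual cue minimizes the
same objective with the ``r_h`` block of the observation masked out; the
recalled dynamics vector is the top-down prediction for that block, and a
rollout through the frozen DPC network reproduces the stored sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .model import DPCParameters, hypernet_forward, mix_transitions, transition_mean, decode_image

__all__ = [
    "MemoryParameters",
    "init_memory",
    "memory_infer",
    "memory_store",
    "recall_from_cue",
    "rollout_recall",
    "rf_positions",
    "CrossCorrResult",
    "rf_distance_crosscorr",
    "peak_lag_slope",
    "crosscorr_difference_slope",
]


@dataclass
class MemoryParameters:
    """Associative-memory weights and hyperparameters.

    G : ``(N + N_h, P)`` synaptic matrix predicting the bound state from m.
    lambda_m : ridge penalty on the memory vector.
    eta_G : storage (Hebbian) learning rate.
    sigma_m2 : observation variance of the memory likelihood (scale of the
        prediction-error term; kept at 1 in the loss above).
    """

    G: np.ndarray
    lambda_m: float = 0.1
    eta_G: float = 0.01
    sigma_m2: float = 1.0

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2 or self.G.shape[1] < 1:
            raise ValueError("G must be (N + N_h, P) with P >= 1")
        if self.eta_G <= 0:
            raise ValueError("eta_G must be positive")
        if self.lambda_m < 0:
            raise ValueError("lambda_m must be nonnegative")

    @property
    def P(self) -> int:
        return self.G.shape[1]


def init_memory(
    n_bound: int,
    P: int | None = None,
    rng: np.random.Generator | int = 0,
    *,
    scale: float = 1e-3,
    lambda_m: float = 0.1,
    eta_G: float = 0.01,
) -> MemoryParameters:
    """Fresh memory with small random synapses (near-null recall)."""

    rng = np.random.default_rng(rng)
    P = n_bound if P is None else P
    G = scale * rng.standard_normal((n_bound, P))
    return MemoryParameters(G=G, lambda_m=lambda_m, eta_G=eta_G)


def memory_infer(
    s: np.ndarray,
    G: np.ndarray,
    lambda_m: float = 0.1,
    *,
    max_iters: int = 5000,
    tol: float = 1e-12,
) -> np.ndarray:
    """MAP memory vector: minimize ``||s - G m||^2 + lambda_m ||m||^2``.

    Gradient descent with a step size of ``1 / L`` (``L`` the gradient's
    Lipschitz constant); for this quadratic objective the iterate converges
    to the ridge solution ``(G^T G + lambda_m I)^{-1} G^T s``.
    """

    s = np.asarray(s, dtype=float)
    G = np.asarray(G, dtype=float)
    if G.shape[0] != s.shape[0]:
        raise ValueError("s and G row dimensions disagree")
    P = G.shape[1]
    m = np.zeros(P)
    L = 2.0 * (np.linalg.norm(G, 2) ** 2 + lambda_m)
    if L == 0:
        return m
    step = 1.0 / L
    for _ in range(max_iters):
        g = 2.0 * (G.T @ (G @ m - s) + lambda_m * m)
        m_new = m - step * g
        if np.max(np.abs(m_new - m)) < tol:
            m = m_new
            break
        m = m_new
    return m


def memory_store(
    mem: MemoryParameters,
    r0_hat: np.ndarray,
    rh_hat: np.ndarray,
    n_reps: int = 5,
    eta_G: float | None = None,
) -> tuple[MemoryParameters, np.ndarray]:
    """Store an episode by repeated inference + Hebbian updates of ``G``.

    Per repetition: infer ``m_hat`` from the current ``G``, then
    ``G <- G + 2 eta_G (s - G m_hat) m_hat^T`` (gradient descent on the
    memory loss; presynaptic ``m_hat`` times postsynaptic prediction
    error).  Returns the updated memory and the per-repetition
    reconstruction errors ``||s - G m_hat||``.
    """

    eta = mem.eta_G if eta_G is None else eta_G
    s = np.concatenate([np.asarray(r0_hat, float), np.asarray(rh_hat, float)])
    G = mem.G.copy()
    errors = np.zeros(n_reps)
    for rep in range(n_reps):
        m_hat = memory_infer(s, G, mem.lambda_m)
        resid = s - G @ m_hat
        errors[rep] = np.linalg.norm(resid)
        if eta > 0:
            G = G + 2.0 * eta * np.outer(resid, m_hat)
    out = MemoryParameters(G=G, lambda_m=mem.lambda_m, eta_G=mem.eta_G, sigma_m2=mem.sigma_m2)
    return out, errors


def recall_from_cue(
    mem: MemoryParameters,
    r0_cue: np.ndarray,
    n_first: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cue-triggered recall of the dynamics vector.

    Minimizes ``||s_tilde - b . (G m)||^2 + lambda_m ||m||^2`` where
    ``s_tilde = [r0_cue; 0]`` and the binary mask ``b`` keeps only the
    first ``n_first`` (content) rows — prediction errors on the missing
    ``r_h`` block are ignored.  The recalled dynamics vector is the
    masked-out block of the top-down prediction ``G m_tilde``.
    """

    r0_cue = np.asarray(r0_cue, dtype=float)
    N = r0_cue.shape[0] if n_first is None else n_first
    if not 0 < N < mem.G.shape[0]:
        raise ValueError("cue length must be positive and smaller than the bound state")
    m_tilde = memory_infer(r0_cue[:N], mem.G[:N], mem.lambda_m)
    rh_recalled = mem.G[N:] @ m_tilde
    return m_tilde, rh_recalled


def rollout_recall(
    params: DPCParameters,
    r0_hat: np.ndarray,
    rh_recalled: np.ndarray,
    T: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a sequence from a content cue and recalled dynamics.

    Iterates the top-down dynamics from ``r0_hat`` with ``rh_recalled``
    held fixed and decodes each state through ``U``.  Returns
    ``(frames (T, M), responses (T, N))``.
    """

    N = params.U.shape[1]
    r = np.zeros((T, N))
    r[0] = np.asarray(r0_hat, dtype=float)
    if T > 1:
        w = hypernet_forward(np.asarray(rh_recalled, dtype=float), params.theta)
        V = mix_transitions(w, params.V)
        for t in range(1, T):
            r[t] = transition_mean(r[t - 1], V)
    frames = decode_image(r, params.U)
    return frames, r


# ---------------------------------------------------------------------------
# Cross-correlation versus receptive-field distance (recall signature)
# ---------------------------------------------------------------------------


def rf_positions(U: np.ndarray, frame_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Receptive-field centers as centroids of ``|column of U|``.

    Returns ``(positions (N, 2) as (x, y), valid mask)``; columns with no
    energy are marked invalid.
    """

    H, W = frame_shape
    N = U.shape[1]
    pos = np.full((N, 2), np.nan)
    valid = np.zeros(N, dtype=bool)
    ys, xs = np.mgrid[0:H, 0:W]
    for i in range(N):
        wgt = np.abs(U[:, i]).reshape(H, W)
        total = wgt.sum()
        if total > 0:
            pos[i] = [(wgt * xs).sum() / total, (wgt * ys).sum() / total]
            valid[i] = True
    return pos, valid


@dataclass
class CrossCorrResult:
    """Pairwise response cross-correlations binned by RF distance."""

    pairs: pd.DataFrame  # columns: i, j, distance, peak_lag, peak_corr
    xcorr: np.ndarray  # (n_pairs, 2 * max_lag + 1)
    lags: np.ndarray
    n_excluded: int


def _normalized_xcorr(xa: np.ndarray, xb: np.ndarray, max_lag: int) -> np.ndarray:
    """Cross-correlation of unit-variance series at integer lags.

    Positive lag means ``xb`` fires after ``xa``.
    """

    T = len(xa)
    a = (xa - xa.mean()) / xa.std()
    b = (xb - xb.mean()) / xb.std()
    out = np.zeros(2 * max_lag + 1)
    for idx, lag in enumerate(range(-max_lag, max_lag + 1)):
        if lag >= 0:
            seg = a[: T - lag] * b[lag:]
        else:
            seg = a[-lag:] * b[: T + lag]
        out[idx] = seg.sum() / (T - abs(lag))
    return out


def rf_distance_crosscorr(
    responses: np.ndarray,
    U: np.ndarray,
    frame_shape: tuple[int, int],
    *,
    max_lag: int = 3,
    motion_axis: int = 0,
    direction_sign: float = 1.0,
) -> CrossCorrResult:
    """Pairwise response cross-correlation as a function of RF distance.

    ``responses`` is ``(T, N)``.  For each pair of active neurons the pair
    is ordered along the motion axis (``motion_axis=0`` is x; flip with
    ``direction_sign=-1`` for motion toward decreasing coordinates), so a
    traveling wave of activity yields peak lags that grow with RF
    separation.  Zero-variance or zero-filter neurons are excluded and
    counted.
    """

    R = np.asarray(responses, dtype=float)
    T, N = R.shape
    pos, valid_rf = rf_positions(U, frame_shape)
    active = R.std(axis=0) > 1e-10
    keep = valid_rf & active
    n_excluded = int(N - keep.sum())
    idx = np.where(keep)[0]
    coord = direction_sign * pos[:, motion_axis]

    rows, corrs = [], []
    for a_i in range(len(idx)):
        for b_i in range(a_i + 1, len(idx)):
            i, j = idx[a_i], idx[b_i]
            first, second = (i, j) if coord[i] <= coord[j] else (j, i)
            dist = abs(coord[i] - coord[j])
            xc = _normalized_xcorr(R[:, first], R[:, second], max_lag)
            peak = int(np.argmax(xc)) - max_lag
            rows.append(
                {"i": first, "j": second, "distance": dist, "peak_lag": peak,
                 "peak_corr": float(xc.max())}
            )
            corrs.append(xc)
    pairs = pd.DataFrame(rows)
    xcorr = np.asarray(corrs) if corrs else np.zeros((0, 2 * max_lag + 1))
    return CrossCorrResult(
        pairs=pairs, xcorr=xcorr, lags=np.arange(-max_lag, max_lag + 1), n_excluded=n_excluded
    )


def peak_lag_slope(result: CrossCorrResult) -> float:
    """Linear-regression slope of cross-correlation peak lag vs RF distance."""

    if len(result.pairs) < 2:
        raise ValueError("need at least two pairs")
    fit = linregress(result.pairs["distance"], result.pairs["peak_lag"])
    return float(fit.slope)


def crosscorr_difference_slope(
    before: CrossCorrResult, after: CrossCorrResult, n_bins: int = 4
) -> float:
    """Peak-lag slope of the "After minus Before" conditioning difference.

    Pairs (common to both results) are binned by RF distance; within each
    bin the difference correlograms are averaged and the lag of the
    averaged curve's peak is taken.  The slope of peak lag against bin
    distance is returned; a positive slope is the sequential-recall
    signature (farther neuron pairs fire with longer lags after
    conditioning).  Binning before peak-picking suppresses the
    integer-lag quantization noise of single pairs.
    """

    if len(before.pairs) != len(after.pairs):
        raise ValueError("before/after results must cover the same pairs")
    diff = after.xcorr - before.xcorr
    d = np.asarray(after.pairs["distance"], dtype=float)
    edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    centers, peaks = [], []
    for i in range(n_bins):
        hi_inclusive = i == n_bins - 1
        mask = (d >= edges[i]) & ((d <= edges[i + 1]) if hi_inclusive else (d < edges[i + 1]))
        if mask.sum() < 2:
            continue
        curve = diff[mask].mean(axis=0)
        peaks.append(after.lags[int(np.argmax(curve))])
        centers.append(d[mask].mean())
    if len(centers) < 2:
        raise ValueError("not enough populated distance bins")
    fit = linregress(centers, peaks)
    return float(fit.slope)
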