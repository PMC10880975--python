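"""Response analysis: receptive fields, timescales, decoding.

* Reverse correlation: space-time receptive fields (STRFs) as the
  response-weighted average of the preceding stimulus window (the model
  analogue of a spike-triggered average).
* Space-time (X-T / Y-T) maps: collapse of the STRF cube along the axis
  whose marginal profile is time-invariant.
* Intrinsic timescales: population-averaged single-neuron autocorrelation
  and an exponential-decay fit ``rho(k) = a exp(-k/tau) + b``.
* Decoding harness: stratified cross-validated RBF-kernel SVM accuracy
  with a majority-label chance level, plus a small PCA projection utility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "compute_strf",
    "collapse_strf_xt",
    "AutocorrResult",
    "autocorrelation",
    "ExponentialFit",
    "fit_exponential_decay",
    "DecodeResult",
    "crossval_decode",
    "pca_project",
]


def compute_strf(stimuli: np.ndarray, responses: np.ndarray, tau: int = 7) -> np.ndarray:
    """Space-time receptive fields by reverse correlation.

    ``stimuli`` is ``(J, T, M)`` and ``responses`` ``(J, T, N)`` aligned to
    it.  For each neuron ``i``::

        STRF_i = 1/(J (T - tau)) * sum_j sum_{t=tau}^{T-1}
                 r_{t,i,j} * I_{t-tau : t-1, j}

    Returns an array ``(N, tau, M)`` whose lag axis is ordered oldest
    first: index ``l`` corresponds to the frame at ``t - tau + l``.
    """

    I = np.asarray(stimuli, dtype=float)
    R = np.asarray(responses, dtype=float)
    if I.ndim != 3 or R.ndim != 3 or I.shape[:2] != R.shape[:2]:
        raise ValueError("stimuli (J, T, M) and responses (J, T, N) must be aligned")
    J, T, M = I.shape
    N = R.shape[2]
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if T <= tau:
        raise ValueError(f"need T > tau, got T={T}, tau={tau}")
    strf = np.empty((N, tau, M))
    r_win = R[:, tau:T, :]  # (J, T - tau, N)
    for lag in range(tau):
        strf[:, lag, :] = np.einsum("jti,jtm->im", r_win, I[:, lag : T - tau + lag, :])
    strf /= J * (T - tau)
    return strf


def collapse_strf_xt(
    strf: np.ndarray, frame_shape: tuple[int, int]
) -> tuple[np.ndarray, str]:
    """Collapse an STRF cube to a space-time map.

    ``strf`` is ``(tau, M)`` for one neuron.  Each lag is reshaped to
    ``(H, W)``; the cube is summed over the axis whose (absolute-value,
    per-lag-normalized) marginal profile varies least across lags — that
    axis carries time-invariant structure, so collapsing it preserves the
    space-time orientation.  Ties collapse the Y (row) axis.  Returns
    ``(map, collapsed_axis)`` where ``map`` has shape ``(space, tau)`` and
    ``collapsed_axis`` is ``"y"`` or ``"x"``.
    """

    strf = np.asarray(strf, dtype=float)
    H, W = frame_shape
    if strf.ndim != 2 or strf.shape[1] != H * W:
        raise ValueError("strf must be (tau, H*W) for a single neuron")
    tau = strf.shape[0]
    cube = strf.reshape(tau, H, W)

    def lag_variance(profiles: np.ndarray) -> float:
        # profiles: (tau, n_space) absolute marginals; normalize each lag
        totals = profiles.sum(axis=1, keepdims=True)
        norm = np.where(totals > 0, profiles / np.maximum(totals, 1e-300), 1.0 / profiles.shape[1])
        return float(np.mean(np.var(norm, axis=0)))

    var_y = lag_variance(np.abs(cube).sum(axis=2))  # y-profile per lag
    var_x = lag_variance(np.abs(cube).sum(axis=1))  # x-profile per lag
    # collapse the axis whose profile is most time-invariant; prefer Y on ties
    axis = "y" if var_y <= var_x else "x"
    if axis == "y":
        xt = cube.sum(axis=1).T  # (W, tau)
    else:
        xt = cube.sum(axis=2).T  # (H, tau)
    return xt, axis


@dataclass
class AutocorrResult:
    """Population-averaged autocorrelation and (optionally) its decay fit."""

    lags: np.ndarray
    rho: np.ndarray
    n_neurons: int
    n_trials: int
    n_excluded: int
    fit: "ExponentialFit | None" = None


def autocorrelation(responses: np.ndarray, k_max: int) -> AutocorrResult:
    """Mean single-neuron autocorrelation across neurons and trials.

    ``responses`` is ``(J, T, N)`` (trials x time x neurons).  Per neuron
    and trial, the series is centered by its mean and normalized by its
    standard deviation (so ``rho(0) = 1``); the lagged products are
    averaged with an unbiased ``1/(T-k)`` factor and then averaged across
    all neuron/trial pairs.  Pairs with zero variance are excluded and
    counted in ``n_excluded``.
    """

    X = np.asarray(responses, dtype=float)
    if X.ndim != 3:
        raise ValueError("responses must be (trials, time, neurons)")
    J, T, N = X.shape
    if k_max >= T:
        raise ValueError("need T > k_max")
    mu = X.mean(axis=1, keepdims=True)
    xc = X - mu
    sd2 = (xc**2).mean(axis=1)  # (J, N) variance (mean of squared deviations)
    valid = sd2 > 1e-24
    n_excluded = int(np.size(valid) - np.count_nonzero(valid))
    if not np.any(valid):
        raise ValueError("all neuron/trial series have zero variance")
    rho = np.empty(k_max + 1)
    for k in range(k_max + 1):
        num = np.sum(xc[:, : T - k, :] * xc[:, k:, :], axis=1)  # (J, N)
        rho_k = num / ((T - k) * sd2 + (~valid))
        rho[k] = rho_k[valid].mean()
    return AutocorrResult(
        lags=np.arange(k_max + 1), rho=rho, n_neurons=N, n_trials=J, n_excluded=n_excluded
    )


@dataclass
class ExponentialFit:
    """Parameters of ``rho(k) = a exp(-k/tau) + b``."""

    a: float
    b: float
    tau: float
    residual: float
    success: bool
    tau_reliable: bool


def fit_exponential_decay(
    rho: np.ndarray, lags: np.ndarray | None = None
) -> ExponentialFit:
    """Nonlinear least-squares fit of an exponential decay to autocorrelation.

    Multi-start over initial timescales ``tau0 in {0.5, 1, 2, 5, 10}``; the
    start with the smallest residual is kept.  If every start fails, the
    result carries ``success=False`` (no exception).  A near-zero fitted
    amplitude flags ``tau`` as unreliable (degenerate plateau).
    """

    rho = np.asarray(rho, dtype=float)
    lags = np.arange(len(rho)) if lags is None else np.asarray(lags, dtype=float)
    if len(rho) < 4:
        raise ValueError("need at least 4 lag points")

    def f(k, a, b, tau):
        return a * np.exp(-k / tau) + b

    best = None
    for tau0 in (0.5, 1.0, 2.0, 5.0, 10.0):
        try:
            p0 = (rho[0] - rho[-1], rho[-1], tau0)
            popt, _ = curve_fit(
                f, lags, rho, p0=p0, bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
            resid = float(np.linalg.norm(rho - f(lags, *popt)))
            if best is None or resid < best[1]:
                best = (popt, resid)
        except (RuntimeError, ValueError):
            continue
    if best is None:
        return ExponentialFit(np.nan, np.nan, np.nan, np.inf, False, False)
    (a, b, tau), resid = best
    reliable = abs(a) > 1e-6 * max(1.0, abs(b))
    return ExponentialFit(float(a), float(b), float(tau), resid, True, reliable)


@dataclass
class DecodeResult:
    mean_accuracy: float
    sd_accuracy: float
    chance: float
    fold_accuracies: np.ndarray


def crossval_decode(
    features: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 10,
    random_state: int = 0,
) -> DecodeResult:
    """Stratified k-fold accuracy of an RBF-kernel SVM.

    Chance level follows the majority rule: per fold, the count of the most
    frequent label in the test split divided by the split size, averaged
    over folds.  Features are standardized inside each fold's pipeline.
    """

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to decode")
    if counts.min() < n_folds:
        raise ValueError(
            f"need >= {n_folds} samples per class, smallest class has {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    accs, chances = [], []
    for train, test in skf.split(X, y):
        clf = make_pipeline(StandardScaler(), SVC(kernel="rbf"))
        clf.fit(X[train], y[train])
        accs.append(clf.score(X[test], y[test]))
        _, test_counts = np.unique(y[test], return_counts=True)
        chances.append(test_counts.max() / len(test))
    accs = np.asarray(accs)
    return DecodeResult(float(accs.mean()), float(accs.std()), float(np.mean(chances)), accs)


def pca_project(features: np.ndarray, n_components: int = 2, random_state: int = 0):
    """Project features onto their first principal components (visualization)."""

    pca = PCA(n_components=n_components, random_state=random_state)
    coords = pca.fit_transform(np.asarray(features, dtype=float))
    return coords, pca
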