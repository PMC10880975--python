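"""Flash-lag / prediction-postdiction experiment.

A trained two-level network is probed with five-step sequences of
consistent leftward or rightward motion.  The higher-level motion estimate
is either inferred from the first three steps ("with initial trajectory")
or reset to zero ("without initial trajectory"); at the probe step the
input either continues the motion, stops, reverses, or terminates (empty
frame).  The model's percept at the probe step is the top-down
spatiotemporal prediction decoded after prediction-error correction::

    w_bar = H_theta(r_h_hat);  V_bar = sum_k w_bar_k V_k
    percept = U ReLU(V_bar r_hat_2)

and its location is the (positive-rectified) center of mass.  The
displacement between the moving-object percept and the flashed-object
percept is signed so that positive lies along the original trajectory.
The latency sweep records the percept at fixed fractions of the
prediction-error-correction iterations, exposing the early predictive /
late postdictive flip on reversed trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datasets import DIRECTION_NAMES, SequenceBatch
from .inference import InferenceOptions, filter_sequence, infer_step
from .model import DPCParameters, Hyperparameters, decode_image, hypernet_forward, mix_transitions, transition_mean

__all__ = [
    "FlashLagCondition",
    "MOTION_CASES",
    "select_consistent_sequences",
    "center_of_mass",
    "displacement",
    "probe_frame",
    "percept_at_step",
    "flash_lag_table",
    "latency_sweep",
]

MOTION_CASES = ("continuous", "stopped", "reversed", "terminated")


@dataclass(frozen=True)
class FlashLagCondition:
    """One cell of the flash-lag design."""

    trajectory: str = "with_initial"  # or "without_initial"
    motion_case: str = "continuous"
    probe_step: int = 3

    def __post_init__(self) -> None:
        if self.trajectory not in ("with_initial", "without_initial"):
            raise ValueError("trajectory must be 'with_initial' or 'without_initial'")
        if self.motion_case not in MOTION_CASES:
            raise ValueError(f"motion_case must be one of {MOTION_CASES}")


def select_consistent_sequences(dataset: SequenceBatch, length: int = 5) -> SequenceBatch:
    """Extract ``length``-frame subsequences of constant left/right motion.

    Scans each sequence for the first window whose per-frame direction is
    constant and horizontal (no bounce inside the window).  Returns a new
    batch whose ``direction`` labels are the (constant) motion direction;
    warns and returns an empty batch if nothing qualifies.
    """

    dir_t = np.asarray(dataset.labels["direction_t"])
    B, T = dir_t.shape
    horiz = {DIRECTION_NAMES.index("left"), DIRECTION_NAMES.index("right")}
    frames_out, dirs_out = [], []
    for b in range(B):
        for start in range(0, T - length + 1):
            window = dir_t[b, start : start + length]
            if window[0] in horiz and np.all(window == window[0]):
                frames_out.append(dataset.frames[b, start : start + length])
                dirs_out.append(window[0])
                break
    if not frames_out:
        warnings.warn("no consistent horizontal subsequences found", stacklevel=2)
        return SequenceBatch(
            frames=np.zeros((0, length, dataset.frames.shape[2])),
            frame_shape=dataset.frame_shape,
            labels={"direction": np.zeros(0, dtype=int)},
        )
    return SequenceBatch(
        frames=np.stack(frames_out),
        frame_shape=dataset.frame_shape,
        labels={"direction": np.asarray(dirs_out, dtype=int)},
        metadata=dict(dataset.metadata),
    )


def center_of_mass(image: np.ndarray, frame_shape: tuple[int, int]) -> tuple[float, float]:
    """Positive-rectified intensity centroid ``(x, y)``.

    Pixel centers sit at integer coordinates with the origin at the
    top-left; ``x`` is the column, ``y`` the row.  Raises ``ValueError``
    when no pixel is positive.
    """

    H, W = frame_shape
    v = np.asarray(image, dtype=float).reshape(H, W)
    wgt = np.maximum(v, 0.0)
    total = wgt.sum()
    if total <= 0:
        raise ValueError("center of mass undefined: no positive pixel")
    ys, xs = np.mgrid[0:H, 0:W]
    return float((wgt * xs).sum() / total), float((wgt * ys).sum() / total)


def displacement(x_moving: float, x_flash: float, direction: str) -> float:
    """Signed percept displacement; positive lies along the original trajectory."""

    if direction == "right":
        return x_moving - x_flash
    if direction == "left":
        return x_flash - x_moving
    raise ValueError("direction must be 'left' or 'right'")


def probe_frame(frames: np.ndarray, motion_case: str, probe_step: int = 3) -> np.ndarray:
    """Input frame presented at the probe step for a motion case.

    ``frames`` is ``(B, T, M)`` with constant-velocity motion.  Continuous
    shows the true next frame; stopped repeats the frame before the probe;
    reversed shows the object one step back along the trajectory (which,
    at constant speed, is the frame two steps before the probe);
    terminated shows an empty (all-zero) frame.
    """

    if motion_case == "continuous":
        return frames[:, probe_step]
    if motion_case == "stopped":
        return frames[:, probe_step - 1]
    if motion_case == "reversed":
        return frames[:, probe_step - 2]
    if motion_case == "terminated":
        return np.zeros_like(frames[:, 0])
    raise ValueError(f"unknown motion case {motion_case!r}")


def percept_at_step(
    params: DPCParameters,
    hyper: Hyperparameters,
    frames: np.ndarray,
    condition: FlashLagCondition,
    opts: InferenceOptions = InferenceOptions(),
    frame_shape: tuple[int, int] | None = None,
    *,
    flash_stimulus: bool = False,
):
    """Percept image and location at the probe step for one condition.

    Filters the three steps before the probe to obtain ``r_hat_2`` (and,
    with an initial trajectory, the motion estimate ``r_h``), corrects the
    states against the probe-step input, then decodes the top-down
    prediction through the corrected ``r_h``.  With
    ``flash_stimulus=True`` the pre-probe input shows the object only on
    the last step (blank frames before), emulating a flashed object; the
    flash corresponds to the "without initial trajectory, terminated"
    condition.

    Returns ``(percepts, locations, valid)`` where ``locations`` is
    ``(B, 2)`` ``(x, y)`` with NaNs (and ``valid=False``) where the percept
    has no positive pixel.
    """

    X = np.asarray(frames, dtype=float)
    if X.ndim == 2:
        X = X[None]
    B, T, M = X.shape
    p = condition.probe_step
    if T < p + 1 and condition.motion_case == "continuous":
        raise ValueError("sequence too short for a continuous probe")
    if np.allclose(params.U, 0):
        warnings.warn("network filters are all zero; percepts will be empty", stacklevel=2)

    pre = X[:, :p].copy()
    if flash_stimulus:
        pre[:, :-1] = 0.0
    traj = filter_sequence(pre, params, hyper, opts)
    r2 = traj.r_hat[:, -1]
    if condition.trajectory == "with_initial":
        rh = traj.r_h_hat[:, -1]
    else:
        rh = np.zeros_like(traj.r_h_hat[:, -1])

    I_probe = probe_frame(X, condition.motion_case, p)
    _, rh_new, _, _ = infer_step(I_probe, r2, rh, params, hyper, opts)

    w_bar = np.atleast_2d(hypernet_forward(rh_new, params.theta))
    V_bar = mix_transitions(w_bar, params.V)
    percepts = decode_image(transition_mean(r2, V_bar), params.U)

    shape = frame_shape
    if shape is None:
        side = int(round(np.sqrt(M)))
        if side * side != M:
            raise ValueError("frame_shape required for non-square frames")
        shape = (side, side)
    locations = np.full((B, 2), np.nan)
    valid = np.zeros(B, dtype=bool)
    for b in range(B):
        try:
            locations[b] = center_of_mass(percepts[b], shape)
            valid[b] = True
        except ValueError:
            pass
    return percepts, locations, valid


def flash_lag_table(
    params: DPCParameters,
    hyper: Hyperparameters,
    selected: SequenceBatch,
    opts: InferenceOptions = InferenceOptions(),
) -> pd.DataFrame:
    """Displacement of every motion case against the flashed-object percept.

    For both trajectory conditions and all four motion cases, computes the
    percept location at the probe step for each selected sequence and its
    signed displacement relative to the flash percept (the "without
    initial trajectory, terminated" condition with a flashed stimulus).
    Returns a tidy DataFrame with one row per (trajectory, motion_case,
    sequence).
    """

    frames = selected.frames
    dirs = [DIRECTION_NAMES[d] for d in selected.labels["direction"]]
    shape = selected.frame_shape

    flash_cond = FlashLagCondition(trajectory="without_initial", motion_case="terminated")
    _, flash_loc, flash_ok = percept_at_step(
        params, hyper, frames, flash_cond, opts, shape, flash_stimulus=True
    )

    rows = []
    for trajectory in ("with_initial", "without_initial"):
        for case in MOTION_CASES:
            cond = FlashLagCondition(trajectory=trajectory, motion_case=case)
            _, loc, ok = percept_at_step(params, hyper, frames, cond, opts, shape)
            for b in range(len(frames)):
                disp = np.nan
                if ok[b] and flash_ok[b]:
                    disp = displacement(loc[b, 0], flash_loc[b, 0], dirs[b])
                rows.append(
                    {
                        "trajectory": trajectory,
                        "motion_case": case,
                        "sequence": b,
                        "direction": dirs[b],
                        "x_percept": loc[b, 0],
                        "x_flash": flash_loc[b, 0],
                        "displacement": disp,
                    }
                )
    return pd.DataFrame(rows)


def latency_sweep(
    params: DPCParameters,
    hyper: Hyperparameters,
    selected: SequenceBatch,
    fractions: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0),
    opts: InferenceOptions = InferenceOptions(),
    probe_opts: InferenceOptions | None = None,
) -> pd.DataFrame:
    """Percept displacement during error correction on reversed trials.

    Uses the "with initial trajectory, reversed" condition.  The pre-probe
    steps are filtered with ``opts``; the probe step's correction runs with
    ``probe_opts`` (default: ``opts`` with a 30-iteration cap, the model's
    perceptual-processing window), and at each stated fraction of those
    iterations the percept is decoded from the current ``r_h`` and compared
    to the *input* image at the step before the probe; positive
    displacement lies along the original trajectory.  Returns a DataFrame
    with one row per (sequence, fraction).
    """

    if probe_opts is None:
        probe_opts = replace(opts, max_iters=30)
    fractions = tuple(float(f) for f in fractions)
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    iters = [int(round(f * probe_opts.max_iters)) for f in fractions]
    if len(set(iters)) < len(set(fractions)):
        raise ValueError(
            f"max_iters={probe_opts.max_iters} too small to resolve fractions {fractions}"
        )

    frames = selected.frames
    dirs = [DIRECTION_NAMES[d] for d in selected.labels["direction"]]
    shape = selected.frame_shape
    p = 3

    traj = filter_sequence(frames[:, :p], params, hyper, opts)
    r2 = traj.r_hat[:, -1]
    rh = traj.r_h_hat[:, -1]
    I_probe = probe_frame(frames, "reversed", p)
    _, _, _, diag = infer_step(
        I_probe, r2, rh, params, hyper, probe_opts, snapshot_iters=tuple(iters)
    )

    rows = []
    for frac, it in zip(fractions, iters):
        _, rh_snap = diag["snapshots"][it]
        w_bar = np.atleast_2d(hypernet_forward(rh_snap, params.theta))
        percepts = decode_image(
            transition_mean(r2, mix_transitions(w_bar, params.V)), params.U
        )
        for b in range(len(frames)):
            try:
                x_p, _ = center_of_mass(percepts[b], shape)
                x_in, _ = center_of_mass(frames[b, p - 1], shape)
                disp = displacement(x_p, x_in, dirs[b])
            except ValueError:
                disp = np.nan
            rows.append({"sequence": b, "fraction": frac, "displacement": disp})
    return pd.DataFrame(rows)
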