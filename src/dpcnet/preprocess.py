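"""Spatial and temporal whitening of image sequences.

Emulates retinal/LGN preprocessing of natural video: each frame is filtered
in the 2-D frequency domain with the amplitude profile

    W(f) = |f| * exp(-(|f| / f0)^4)

(``f0`` defaults to 0.8 of the Nyquist frequency), which removes the DC
component and flattens the roughly 1/f amplitude spectrum of natural
images while rolling off the highest frequencies.  A first-order temporal
decorrelation filter ``y_t = x_t - alpha * x_{t-1}`` (with ``y_0 = x_0``)
then removes the dominant frame-to-frame correlation.  Both stages are
linear.
"""

from __future__ import annotations

import numpy as np

from .datasets import SequenceBatch

__all__ = ["spatial_whitening_filter", "whiten_sequences"]


def spatial_whitening_filter(shape: tuple[int, int], f0_fraction: float = 0.8) -> np.ndarray:
    """Frequency-domain amplitude filter ``|f| exp(-(f/f0)^4)`` on an H x W grid."""

    H, W = shape
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    f = np.hypot(fy, fx)
    f0 = f0_fraction * 0.5  # Nyquist = 0.5 cycles/pixel
    return f * np.exp(-((f / f0) ** 4))


def whiten_sequences(
    batch,
    frame_shape: tuple[int, int] | None = None,
    *,
    f0_fraction: float = 0.8,
    temporal: bool = True,
    alpha: float = 0.8,
):
    """Whiten a batch of image sequences spatially then temporally.

    ``batch`` may be a :class:`~dpcnet.datasets.SequenceBatch`, an array of
    images ``(B, T, H, W)`` / ``(T, H, W)``, or flattened frames
    ``(B, T, M)`` with ``frame_shape`` given.  Returns an object/array of
    the same kind.  Raises ``ValueError`` when temporal filtering is
    requested on sequences shorter than two frames.
    """

    if isinstance(batch, SequenceBatch):
        if batch.frame_shape is None:
            raise ValueError("SequenceBatch has no frame_shape")
        out = whiten_sequences(
            batch.images(), f0_fraction=f0_fraction, temporal=temporal, alpha=alpha
        )
        B, T = batch.frames.shape[:2]
        meta = dict(batch.metadata)
        meta.update({"whitened": True, "f0_fraction": f0_fraction,
                     "temporal_alpha": alpha if temporal else None})
        return SequenceBatch(
            frames=out.reshape(B, T, -1),
            frame_shape=batch.frame_shape,
            labels=dict(batch.labels),
            metadata=meta,
        )

    X = np.asarray(batch, dtype=float)
    squeeze = False
    if X.ndim == 3 and frame_shape is not None:
        B, T, M = X.shape
        if frame_shape[0] * frame_shape[1] != M:
            raise ValueError("frame_shape inconsistent with frame length")
        out = whiten_sequences(
            X.reshape(B, T, *frame_shape), f0_fraction=f0_fraction, temporal=temporal, alpha=alpha
        )
        return out.reshape(B, T, M)
    if X.ndim == 3:
        X = X[None]
        squeeze = True
    if X.ndim != 4:
        raise ValueError("expected (B, T, H, W), (T, H, W), or (B, T, M) with frame_shape")

    B, T, H, W = X.shape
    if temporal and T < 2:
        raise ValueError("temporal whitening needs at least two frames")

    filt = spatial_whitening_filter((H, W), f0_fraction)
    Y = np.fft.ifft2(np.fft.fft2(X, axes=(-2, -1)) * filt, axes=(-2, -1)).real
    if temporal:
        Z = Y.copy()
        Z[:, 1:] = Y[:, 1:] - alpha * Y[:, :-1]
        Y = Z
    return Y[0] if squeeze else Y
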