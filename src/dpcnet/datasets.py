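"""Synthetic stimulus generators.

Every experiment in the package runs on programmatically generated stimuli
with the statistical structure of the datasets the model is designed for:

* moving-sprite sequences (a drawn-glyph stand-in for moving handwritten
  digits: one sprite translating at fixed speed in one of four cardinal
  directions, reflecting at the frame boundary),
* bouncing-dynamics datasets with either "straight" (reverse) or
  "clockwise" boundary rules, used by the three-level model,
* i.i.d. Gaussian white-noise stimuli for timescale analysis,
* whitened drifting band-pass textures as a surrogate for short natural
  video patches with stable within-sequence motion.

All generators are pure functions of their spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "DIRECTIONS",
    "DIRECTION_NAMES",
    "ImageSequence",
    "SequenceBatch",
    "SpriteDatasetSpec",
    "glyph",
    "GLYPH_NAMES",
    "make_moving_sprites",
    "make_bouncing_dataset",
    "make_white_noise",
    "make_drifting_surrogate",
]


# (row, col) displacement per unit speed; row axis points down
DIRECTIONS: dict[str, tuple[int, int]] = {
    "up": (-1, 0),
    "down": (1, 0),
    "left": (0, -1),
    "right": (0, 1),
}
DIRECTION_NAMES: tuple[str, ...] = ("up", "down", "left", "right")

_STRAIGHT = {"up": "down", "down": "up", "left": "right", "right": "left"}
_CLOCKWISE = {"left": "up", "up": "right", "right": "down", "down": "left"}


@dataclass
class ImageSequence:
    """A single stimulus episode: ``frames`` is ``(T, M)`` row-major."""

    frames: np.ndarray
    frame_shape: tuple[int, int] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[0] < 1:
            raise ValueError("frames must be (T, M) with T >= 1")
        if self.frame_shape is not None:
            h, w = self.frame_shape
            if h * w != self.frames.shape[1]:
                raise ValueError("frame_shape inconsistent with frame length")

    @property
    def n_steps(self) -> int:
        return self.frames.shape[0]

    def images(self) -> np.ndarray:
        if self.frame_shape is None:
            raise ValueError("no frame_shape set")
        return self.frames.reshape(self.n_steps, *self.frame_shape)


@dataclass
class SequenceBatch:
    """A batch of equal-length episodes: ``frames`` is ``(B, T, M)``."""

    frames: np.ndarray
    frame_shape: tuple[int, int] | None = None
    labels: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (B, T, M)")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def n_steps(self) -> int:
        return self.frames.shape[1]

    def __getitem__(self, b: int) -> ImageSequence:
        meta = {k: v[b] for k, v in self.labels.items()}
        meta.update(self.metadata)
        return ImageSequence(self.frames[b], self.frame_shape, meta)

    def __iter__(self) -> Iterator[ImageSequence]:
        for b in range(len(self)):
            yield self[b]

    def images(self) -> np.ndarray:
        if self.frame_shape is None:
            raise ValueError("no frame_shape set")
        B, T, _ = self.frames.shape
        return self.frames.reshape(B, T, *self.frame_shape)


# ---------------------------------------------------------------------------
# Sprite bank: programmatically drawn glyphs standing in for digits
# ---------------------------------------------------------------------------


def _glyph_canvas(size: int) -> np.ndarray:
    return np.zeros((size, size))


def glyph(name: str, size: int = 8) -> np.ndarray:
    """Draw one glyph as a ``size x size`` array with values in [0, 1]."""

    g = _glyph_canvas(size)
    m = size // 2
    thick = max(1, size // 4)
    if name == "bar_v":
        g[:, m - thick // 2 : m - thick // 2 + thick] = 1.0
    elif name == "bar_h":
        g[m - thick // 2 : m - thick // 2 + thick, :] = 1.0
    elif name == "cross":
        g[:, m - 1 : m + 1] = 1.0
        g[m - 1 : m + 1, :] = 1.0
    elif name == "ring":
        yy, xx = np.mgrid[0:size, 0:size]
        rad = np.hypot(yy - (size - 1) / 2, xx - (size - 1) / 2)
        g[(rad <= size / 2 - 0.5) & (rad >= size / 4 - 0.5)] = 1.0
    elif name == "blob":
        yy, xx = np.mgrid[0:size, 0:size]
        rad2 = (yy - (size - 1) / 2) ** 2 + (xx - (size - 1) / 2) ** 2
        g = np.exp(-rad2 / (2 * (size / 4) ** 2))
    elif name == "ell":
        g[:, :thick] = 1.0
        g[-thick:, :] = 1.0
    elif name == "tee":
        g[:thick, :] = 1.0
        g[:, m - thick // 2 : m - thick // 2 + thick] = 1.0
    elif name == "diag":
        for i in range(size):
            g[i, max(0, i - 1) : min(size, i + 1)] = 1.0
    else:
        raise ValueError(f"unknown glyph {name!r}")
    return g


GLYPH_NAMES: tuple[str, ...] = ("bar_v", "bar_h", "cross", "ring", "blob", "ell", "tee", "diag")


@dataclass(frozen=True)
class SpriteDatasetSpec:
    """Specification of a moving-sprite dataset.

    A sprite (one of ``sprite_bank``) translates at fixed ``speed`` in one
    of the four cardinal ``directions``; on hitting the frame boundary its
    direction changes according to ``bounce_rule`` ("straight" reverses,
    "clockwise" rotates left->up->right->down->left).  With
    ``avoid_bounce=True`` the start position is constrained so the path
    never reaches a boundary (used for constant-motion corpora).
    """

    n_sequences: int = 100
    frame_size: int = 18
    T: int = 10
    directions: tuple[str, ...] = DIRECTION_NAMES
    speed: int = 1
    bounce_rule: str = "straight"
    sprite_bank: tuple[str, ...] = GLYPH_NAMES
    sprite_size: int = 8
    avoid_bounce: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sprite_size >= self.frame_size:
            raise ValueError("sprite must be smaller than the frame")
        if self.speed < 1:
            raise ValueError("speed must be >= 1")
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.bounce_rule not in ("straight", "clockwise"):
            raise ValueError("bounce_rule must be 'straight' or 'clockwise'")
        unknown = set(self.directions) - set(DIRECTION_NAMES)
        if unknown:
            raise ValueError(f"unknown directions {unknown}")


def _next_direction(name: str, pos: np.ndarray, speed: int, lo: int, hi: int, rule: str) -> tuple[str, bool]:
    """Resolve the direction for the next move, applying the bounce rule
    (possibly repeatedly, e.g. in a corner) until the move stays in bounds."""

    table = _STRAIGHT if rule == "straight" else _CLOCKWISE
    bounced = False
    for _ in range(4):
        d = np.array(DIRECTIONS[name])
        nxt = pos + speed * d
        if np.all(nxt >= lo) and np.all(nxt <= hi):
            return name, bounced
        name = table[name]
        bounced = True
    raise ValueError("no in-bounds direction found; frame too small for this speed")


def _generate_sprites(spec: SpriteDatasetSpec) -> SequenceBatch:
    rng = np.random.default_rng(spec.rng_seed)
    F, S, T, s = spec.frame_size, spec.sprite_size, spec.T, spec.speed
    hi = F - S
    B = spec.n_sequences
    frames = np.zeros((B, T, F * F))
    dir_code = np.zeros(B, dtype=int)
    dir_t = np.zeros((B, T), dtype=int)
    sprite_id = np.zeros(B, dtype=int)
    bounce_mask = np.zeros((B, T), dtype=bool)
    dir_index = {n: i for i, n in enumerate(DIRECTION_NAMES)}

    for b in range(B):
        name = spec.directions[rng.integers(len(spec.directions))]
        gid = rng.integers(len(spec.sprite_bank))
        sprite = glyph(spec.sprite_bank[gid], S)
        d = np.array(DIRECTIONS[name])
        if spec.avoid_bounce:
            total = s * (T - 1) * d
            lo_start = np.maximum(0, -total)
            hi_start = np.minimum(hi, hi - total)
            if np.any(hi_start < lo_start):
                raise ValueError("cannot avoid bounces: path longer than the frame allows")
            pos = np.array([rng.integers(lo_start[a], hi_start[a] + 1) for a in (0, 1)])
        else:
            pos = np.array([rng.integers(0, hi + 1) for _ in (0, 1)])
        sprite_id[b] = gid
        dir_code[b] = dir_index[name]
        img = np.zeros((F, F))
        img[pos[0] : pos[0] + S, pos[1] : pos[1] + S] = sprite
        frames[b, 0] = img.ravel()
        dir_t[b, 0] = dir_index[name]
        for t in range(1, T):
            name, bounced = _next_direction(name, pos, s, 0, hi, spec.bounce_rule)
            pos = pos + s * np.array(DIRECTIONS[name])
            bounce_mask[b, t] = bounced
            dir_t[b, t] = dir_index[name]
            img = np.zeros((F, F))
            img[pos[0] : pos[0] + S, pos[1] : pos[1] + S] = sprite
            frames[b, t] = img.ravel()

    return SequenceBatch(
        frames=frames,
        frame_shape=(F, F),
        labels={
            "direction": dir_code,
            "direction_t": dir_t,
            "sprite_id": sprite_id,
            "bounce_mask": bounce_mask,
        },
        metadata={
            "direction_names": DIRECTION_NAMES,
            "speed": s,
            "bounce_rule": spec.bounce_rule,
            "sprite_bank": spec.sprite_bank,
        },
    )


def make_moving_sprites(spec: SpriteDatasetSpec) -> SequenceBatch:
    """Moving-sprite dataset: one sprite per sequence, fixed speed, four
    cardinal directions, reflecting boundaries.  No whitening is applied.

    Labels: initial ``direction`` (index into ``DIRECTION_NAMES``),
    per-frame ``direction_t``, ``sprite_id`` and a per-frame boolean
    ``bounce_mask`` marking frames whose move followed a bounce.
    """

    return _generate_sprites(spec)


def make_bouncing_dataset(spec: SpriteDatasetSpec) -> SequenceBatch:
    """Longer sprite sequences guaranteed to contain bounce events.

    Use ``bounce_rule='straight'`` or ``'clockwise'``; typical settings are
    ``T=20, speed=2`` which yield at least two bounces per sequence.
    """

    if spec.avoid_bounce:
        raise ValueError("a bouncing dataset cannot avoid bounces")
    reach = spec.speed * (spec.T - 1)
    if reach < 2 * (spec.frame_size - spec.sprite_size):
        raise ValueError("T too short to guarantee bounce events at this speed")
    return _generate_sprites(spec)


def make_white_noise(
    T: int,
    M: int,
    variance: float = 0.0075,
    rng_seed: int | np.random.Generator = 0,
    *,
    n_sequences: int = 1,
) -> SequenceBatch:
    """I.i.d. Gaussian pixel noise, ``N(0, variance)`` per pixel and step."""

    if variance <= 0:
        raise ValueError("variance must be positive")
    rng = np.random.default_rng(rng_seed)
    frames = rng.standard_normal((n_sequences, T, M)) * np.sqrt(variance)
    side = int(round(np.sqrt(M)))
    shape = (side, side) if side * side == M else None
    return SequenceBatch(frames=frames, frame_shape=shape, metadata={"variance": variance})


def _bandpass_texture(size: int, rng: np.random.Generator) -> np.ndarray:
    """Random texture with an annular (band-pass) spatial spectrum."""

    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    mask = (f > 0.06) & (f < 0.25)
    spec = (rng.standard_normal((size, size)) + 1j * rng.standard_normal((size, size))) * mask
    tex = np.fft.ifft2(spec).real
    tex /= max(tex.std(), 1e-12)
    return tex


def _fourier_shift(img: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Circularly translate an image by a (possibly subpixel) offset."""

    H, W = img.shape
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    phase = np.exp(-2j * np.pi * (fy * dy + fx * dx))
    return np.fft.ifft2(np.fft.fft2(img) * phase).real


def make_drifting_surrogate(
    n_sequences: int,
    frame_size: int = 16,
    T: int = 10,
    rng_seed: int | np.random.Generator = 0,
    *,
    speed_range: tuple[float, float] = (0.5, 1.5),
    zero_velocity: bool = False,
    whiten: bool = True,
) -> SequenceBatch:
    """Drifting band-pass textures as a natural-patch surrogate.

    Each sequence is a random band-pass texture translating (circularly,
    with subpixel Fourier shifts) at a per-sequence constant velocity whose
    direction is uniform on the circle; the batch is then passed through
    :func:`dpcnet.preprocess.whiten_sequences` unless ``whiten=False``.
    Emulates short natural-video patches with stable within-sequence
    dynamics.  Labels: ``velocity`` as ``(dy, dx)`` per sequence.
    """

    rng = np.random.default_rng(rng_seed)
    F = frame_size
    frames = np.zeros((n_sequences, T, F * F))
    velocity = np.zeros((n_sequences, 2))
    for b in range(n_sequences):
        tex = _bandpass_texture(F, rng)
        if zero_velocity:
            v = np.zeros(2)
        else:
            ang = rng.uniform(0, 2 * np.pi)
            spd = rng.uniform(*speed_range)
            v = spd * np.array([np.sin(ang), np.cos(ang)])
        velocity[b] = v
        for t in range(T):
            frames[b, t] = _fourier_shift(tex, t * v[0], t * v[1]).ravel()
    batch = SequenceBatch(
        frames=frames,
        frame_shape=(F, F),
        labels={"velocity": velocity},
        metadata={"whitened": whiten},
    )
    if whiten:
        from .preprocess import whiten_sequences

        batch = whiten_sequences(batch)
    return batch
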