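"""Paired data augmentation.

Each enabled operation fires independently with a configurable
probability, and the *same* sampled transform is applied to both images
of a pair (and its mask), so alignment is never broken.  Defaults follow
the training protocol: up to +/-20 px translation (horizontal, vertical
or diagonal), horizontal/vertical mirroring, and up to +/-15 degrees of
rotation.  Out-of-frame regions are filled by reflection — zero fill
would fabricate dark borders that read as spurious "hard" tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import ImagePair

__all__ = ["AugmentConfig", "augment_pair", "sample_transform", "apply_transform"]


@dataclass(frozen=True)
class AugmentConfig:
    probability: float = 0.5
    max_translate: int = 20
    flip_horizontal: bool = True
    flip_vertical: bool = True
    max_rotate: float = 15.0
    fill: str = "reflect"

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if self.max_translate < 0 or self.max_rotate < 0:
            raise ValueError("translation and rotation bounds must be >= 0")


@dataclass(frozen=True)
class Transform:
    """One concrete sampled augmentation (applied identically to both images)."""

    dx: int = 0
    dy: int = 0
    flip_h: bool = False
    flip_v: bool = False
    angle: float = 0.0


def sample_transform(config: AugmentConfig, rng: np.random.Generator) -> Transform:
    """Draw one transform; order of draws is fixed (translation, flips,
    rotation) so seeds reproduce across versions."""
    dx = dy = 0
    if rng.random() < config.probability and config.max_translate > 0:
        m = config.max_translate
        dx = int(rng.integers(-m, m + 1))
        dy = int(rng.integers(-m, m + 1))
    flip_h = config.flip_horizontal and rng.random() < config.probability
    flip_v = config.flip_vertical and rng.random() < config.probability
    angle = 0.0
    if rng.random() < config.probability and config.max_rotate > 0:
        angle = float(rng.uniform(-config.max_rotate, config.max_rotate))
    return Transform(dx, dy, flip_h, flip_v, angle)


def _shift(img: np.ndarray, dx: int, dy: int, fill: str) -> np.ndarray:
    h, w = img.shape[:2]
    pad_y = (max(dy, 0), max(-dy, 0))
    pad_x = (max(dx, 0), max(-dx, 0))
    pads = (pad_y, pad_x) + ((0, 0),) * (img.ndim - 2)
    mode = "reflect" if fill == "reflect" else "constant"
    padded = np.pad(img, pads, mode=mode)
    y0 = pad_y[1]
    x0 = pad_x[1]
    return padded[y0 : y0 + h, x0 : x0 + w]


def apply_transform(img: np.ndarray, t: Transform, fill: str = "reflect",
                    order: int = 1) -> np.ndarray:
    """Apply translation -> flips -> rotation; dtype preserved."""
    out = img
    if t.dx or t.dy:
        out = _shift(out, t.dx, t.dy, fill)
    if t.flip_h:
        out = out[:, ::-1]
    if t.flip_v:
        out = out[::-1]
    if t.angle != 0.0:
        dtype = out.dtype
        mode = "reflect" if fill == "reflect" else "constant"
        rot = ndimage.rotate(
            out.astype(np.float64), t.angle, axes=(1, 0),
            reshape=False, order=order, mode=mode,
        )
        if np.issubdtype(dtype, np.integer):
            info = np.iinfo(dtype)
            rot = np.clip(np.rint(rot), info.min, info.max)
        out = rot.astype(dtype)
    return np.ascontiguousarray(out)


def augment_pair(pair: ImagePair, config: AugmentConfig, seed: int) -> ImagePair:
    """Jointly augment a (B-mode, elastogram[, mask]) pair; deterministic
    for fixed seed."""
    rng = np.random.default_rng(seed)
    t = sample_transform(config, rng)
    bmode = apply_transform(pair.bmode, t, config.fill)
    elasto = apply_transform(pair.elasto, t, config.fill)
    mask = None
    if pair.mask is not None:
        mask = apply_transform(
            pair.mask.astype(np.uint8), t, config.fill, order=0
        ).astype(bool)
    return ImagePair(bmode, elasto, mask)
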