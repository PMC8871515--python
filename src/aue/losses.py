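"""Training objectives.

The full generator objective combines, over the discriminator scales i:

    sum_i L_GAN(G, D_i)  +  alpha * sum_i L_FM(G, D_i)  +  beta * L_color

where L_GAN is the conditional adversarial loss, L_FM matches
discriminator intermediate features between real and generated pairs,
and L_color compares Gaussian-blurred versions of the generated and real
elastograms — blurring suppresses texture so only brightness, contrast
and the large-scale color distribution are penalized.  The color
distance is the sum of an RMS (Euclidean) and a mean-absolute term, both
normalized per pixel and channel so values are resolution-independent.
An optional perceptual loss taps five layers of a pluggable feature
extractor with weights [1/32, 1/16, 1/8, 1/4, 1].

Every function accepts either numpy arrays (returning floats) or
autograd tensors (returning scalar tensors usable in training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d

from .nn import Tensor, conv2d as t_conv2d, pad2d
from .nn.modules import Conv2d, Module

__all__ = [
    "BlurParams",
    "LossWeights",
    "gaussian_kernel",
    "gaussian_blur",
    "color_loss",
    "gan_loss",
    "feature_matching_loss",
    "perceptual_loss",
    "total_generator_loss",
    "RandomFeatureExtractor",
    "PERCEPTUAL_LAYER_WEIGHTS",
]

#: Per-layer weights for the five perceptual-loss tap points.
PERCEPTUAL_LAYER_WEIGHTS = (1 / 32, 1 / 16, 1 / 8, 1 / 4, 1.0)


@dataclass(frozen=True)
class BlurParams:
    """Gaussian kernel spec for the color loss: odd k x l window, sigma > 0."""

    kernel: tuple[int, int] = (21, 21)
    sigma: float = 3.0
    padding: str = "reflect"

    def __post_init__(self):
        k, l = self.kernel
        if k < 3 or l < 3 or k % 2 == 0 or l % 2 == 0:
            raise ValueError(f"kernel sides must be odd and >= 3, got {self.kernel}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class LossWeights:
    """Weights of the combined objective (alpha: feature matching,
    beta: color, lambda_perceptual: optional perceptual term)."""

    alpha: float = 10.0
    beta: float = 10.0
    lambda_perceptual: float = 0.0
    perceptual_layer_weights: tuple[float, ...] = PERCEPTUAL_LAYER_WEIGHTS
    gan_mode: str = "bce"

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.lambda_perceptual < 0:
            raise ValueError("loss weights must be >= 0")
        if self.gan_mode not in ("bce", "lsgan"):
            raise ValueError(f"unknown GAN mode {self.gan_mode!r}")


def gaussian_kernel(params: BlurParams) -> np.ndarray:
    """Separable normalized Gaussian window (sums to exactly 1)."""
    k, l = params.kernel
    gy = np.exp(-0.5 * ((np.arange(k) - (k - 1) / 2) / params.sigma) ** 2)
    gx = np.exp(-0.5 * ((np.arange(l) - (l - 1) / 2) / params.sigma) ** 2)
    kern = np.outer(gy, gx)
    return (kern / kern.sum()).astype(np.float64)


def gaussian_blur(img, params: BlurParams = BlurParams()):
    """Per-channel 2-D Gaussian blur with reflect padding.

    Accepts (H,W), (H,W,C) numpy arrays or (B,C,H,W) tensors; constant
    images pass through unchanged because the kernel is normalized.
    """
    kern = gaussian_kernel(params)
    k, l = params.kernel
    if isinstance(img, Tensor):
        b, c, h, w = img.shape
        x = img.reshape(b * c, 1, h, w)
        x = pad2d(x, (k // 2, l // 2), params.padding if params.padding != "zero" else "zeros")
        out = t_conv2d(x, Tensor(kern[None, None]))
        return out.reshape(b, c, h, w)
    arr = np.asarray(img, dtype=np.float64)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    pad_mode = "reflect" if params.padding == "reflect" else "constant"
    padded = np.pad(arr, ((k // 2, k // 2), (l // 2, l // 2), (0, 0)), mode=pad_mode)
    out = np.stack(
        [convolve2d(padded[:, :, ch], kern, mode="valid") for ch in range(arr.shape[2])],
        axis=2,
    )
    return out[:, :, 0] if squeeze else out


def color_loss(x, y, params: BlurParams = BlurParams()):
    """Blurred color-distribution distance: RMS + mean-absolute.

    Both terms are normalized by the pixel-channel count, so two uniform
    images differing by 1 in every channel score exactly 2 regardless of
    resolution.  Symmetric in its arguments.
    """
    if isinstance(x, Tensor) or isinstance(y, Tensor):
        if x.shape != y.shape:
            raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
        d = gaussian_blur(x, params) - gaussian_blur(y, params)
        return ((d**2).mean() + 1e-12).sqrt() + d.abs().mean()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    d = gaussian_blur(x, params) - gaussian_blur(y, params)
    return float(np.sqrt(np.mean(d**2)) + np.mean(np.abs(d)))


def gan_loss(logits, target_real: bool, mode: str = "bce"):
    """Adversarial loss for one patch-logit map, averaged over patches.

    ``bce`` is the saturating log objective via sigmoid cross-entropy;
    ``lsgan`` uses least-squares targets 1 (real) / 0 (fake).
    """
    if mode not in ("bce", "lsgan"):
        raise ValueError(f"unknown GAN mode {mode!r}")
    t = logits if isinstance(logits, Tensor) else Tensor(np.asarray(logits))
    if not np.all(np.isfinite(t.data)):
        raise ValueError("non-finite logits")
    if mode == "bce":
        out = (-t).softplus().mean() if target_real else t.softplus().mean()
    else:
        target = 1.0 if target_real else 0.0
        out = ((t - target) ** 2).mean()
    return out if isinstance(logits, Tensor) else float(out.data)


def feature_matching_loss(feats_real, feats_fake):
    """Mean L1 between discriminator activations, averaged over layers
    and scales; real features are treated as constants."""
    if len(feats_real) != len(feats_fake):
        raise ValueError("scale count mismatch between real and fake features")
    terms = []
    for fr_scale, ff_scale in zip(feats_real, feats_fake):
        if len(fr_scale) != len(ff_scale):
            raise ValueError("layer count mismatch between real and fake features")
        for fr, ff in zip(fr_scale, ff_scale):
            fr = fr.detach() if isinstance(fr, Tensor) else Tensor(np.asarray(fr))
            ff = ff if isinstance(ff, Tensor) else Tensor(np.asarray(ff))
            if fr.shape != ff.shape:
                raise ValueError(f"feature shape mismatch: {fr.shape} vs {ff.shape}")
            terms.append((ff - fr).abs().mean())
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def perceptual_loss(x, y, extractor, layer_weights=PERCEPTUAL_LAYER_WEIGHTS):
    """Weighted mean-L1 between tapped extractor features of x and y.

    The extractor is pluggable: any callable mapping an image tensor to a
    list of feature tensors (a pretrained network, or a fixed seeded
    random stack for self-contained runs).
    """
    fx = extractor(x)
    fy = extractor(y)
    if len(fx) != len(layer_weights) or len(fy) != len(layer_weights):
        raise ValueError(
            f"extractor taps {len(fx)} layers but {len(layer_weights)} weights given"
        )
    total = None
    for w, a, b in zip(layer_weights, fx, fy):
        term = (a - b.detach()).abs().mean() * float(w)
        total = term if total is None else total + term
    return total


class RandomFeatureExtractor(Module):
    """Fixed seeded 5-stage convolutional feature stack.

    A deterministic stand-in extractor (synthetic, not pretrained) for
    the perceptual loss and FID when no pretrained network is available:
    five stride-2 conv+ReLU stages tapped after each activation.  Weights
    are frozen.
    """

    def __init__(self, in_channels: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        chans = [in_channels, 16, 32, 64, 64, 64]
        self.stages = [
            Conv2d(chans[i], chans[i + 1], 3, stride=2, padding=1, rng=rng)
            for i in range(5)
        ]
        for p in self.parameters():
            p.requires_grad = False

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = []
        for conv in self.stages:
            x = conv(x).relu()
            feats.append(x)
        return feats

    def embed(self, images: np.ndarray) -> np.ndarray:
        """Global-average-pooled top features for a stack of images
        (N,H,W,3 in [0,255]) — the FID embedding."""
        x = Tensor(np.transpose(images, (0, 3, 1, 2)) / 127.5 - 1.0)
        top = self.forward(x)[-1]
        return top.data.mean(axis=(2, 3))


def total_generator_loss(
    gan_terms,
    fm_terms,
    color_term,
    weights: LossWeights,
    perceptual_term=None,
):
    """Combine per-scale GAN and feature-matching terms with the color
    (and optional perceptual) terms; returns (total, breakdown).

    The color loss is computed once on images rather than per
    discriminator scale; multiplying it into the scale sum would only
    rescale beta.
    """
    if len(gan_terms) != len(fm_terms):
        raise ValueError("gan_terms and fm_terms must have one entry per scale")
    if weights.alpha < 0 or weights.beta < 0:
        raise ValueError("negative loss weights")

    def tsum(terms):
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        return total

    as_tensor = any(isinstance(t, Tensor) for t in list(gan_terms) + list(fm_terms))
    if not as_tensor:
        gan_terms = [Tensor(np.asarray(float(t))) for t in gan_terms]
        fm_terms = [Tensor(np.asarray(float(t))) for t in fm_terms]
        if not isinstance(color_term, Tensor):
            color_term = Tensor(np.asarray(float(color_term)))
    gan_sum = tsum(list(gan_terms))
    fm_sum = tsum(list(fm_terms))
    total = gan_sum + weights.alpha * fm_sum + weights.beta * color_term
    breakdown = {
        "gan": float(gan_sum.data),
        "feature_matching": float(weights.alpha) * float(fm_sum.data),
        "color": float(weights.beta) * float(
            color_term.data if isinstance(color_term, Tensor) else color_term
        ),
    }
    if perceptual_term is not None:
        total = total + weights.lambda_perceptual * perceptual_term
        breakdown["perceptual"] = float(weights.lambda_perceptual) * float(
            perceptual_term.data if isinstance(perceptual_term, Tensor) else perceptual_term
        )
    # the breakdown is the accounting authority: its entries sum exactly
    breakdown["total"] = float(sum(v for k, v in breakdown.items()))
    if as_tensor:
        return total, breakdown
    return breakdown["total"], breakdown
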