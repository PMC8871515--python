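"""AUE-net architecture.

The generator is an encoder/decoder translation network: a spatial
attention gate on the early features (locating the nodule in the B-mode
texture), three stride-2 down-sampling blocks, nine residual blocks in
the latent space, one spatially-adaptive-denormalization residual block
(AUE-ResBlk) that re-injects the encoder features before decoding, three
up-sampling blocks, a channel attention gate balancing the output color
channels, and a tanh head producing a 3-channel image in [-1, 1].

The discriminator is a multiscale patch discriminator: the (B-mode,
candidate elastogram) pair is concatenated on channels and scored by a
small stack of stride-2 convolutions at each of ``n_scales`` input
resolutions.  Every discriminator convolution is spectral-normalized and
uses Leaky-ReLU; intermediate activations are returned for the
feature-matching loss.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .nn import (
    Tensor,
    concat,
    avg_pool2d,
    resize_bilinear,
    upsample_nearest2d,
)
from .nn.modules import (
    Conv2d,
    InstanceNorm2d,
    LeakyReLU,
    Module,
    ReLU,
    Sequential,
    SpectralNormConv2d,
    Tanh,
)

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "Generator",
    "MultiscaleDiscriminator",
    "SPADE",
    "SpatialAttention",
    "ChannelAttention",
    "spade_denorm",
    "spatial_attention",
    "channel_attention",
]


@dataclass
class GeneratorConfig:
    in_channels: int = 1
    out_channels: int = 3
    base_channels: int = 64
    n_down: int = 3
    n_resblocks: int = 9
    use_spatial_attention: bool = True
    use_channel_attention: bool = True
    use_aue_resblock: bool = True
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_down < 1:
            raise ValueError("n_down must be >= 1")
        if self.n_resblocks < 0:
            raise ValueError("n_resblocks must be >= 0")

    def to_json(self) -> dict:
        return asdict(self)


@dataclass
class DiscriminatorConfig:
    in_channels: int = 4  # condition (1) + candidate (3), channel-concatenated
    base_channels: int = 64
    n_scales: int = 2
    n_layers: int = 3
    spectral_norm: bool = True
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")

    def to_json(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# building blocks


class SpatialAttention(Module):
    """CBAM-style spatial gate: sigmoid conv over channel-pooled statistics.

    The map A = sigmoid(conv7x7([mean_c f; max_c f])) lies in (0, 1) and
    multiplies every channel, letting the network emphasize nodule
    locations.
    """

    def __init__(self, kernel: int = 7, rng: np.random.Generator | None = None):
        self.conv = Conv2d(2, 1, kernel, padding=kernel // 2, pad_mode="reflect",
                           rng=rng)

    def attention_map(self, f: Tensor) -> Tensor:
        pooled = concat([f.mean(axis=1, keepdims=True), f.max(axis=1, keepdims=True)], 1)
        return self.conv(pooled).sigmoid()

    def forward(self, f: Tensor) -> Tensor:
        return f * self.attention_map(f)


class ChannelAttention(Module):
    """CBAM-style channel gate: bottleneck MLP over global avg+max pooling."""

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None):
        hidden = max(channels // reduction, 1)
        self.fc1 = Conv2d(channels, hidden, 1, rng=rng)
        self.fc2 = Conv2d(hidden, channels, 1, rng=rng)

    def attention_weights(self, f: Tensor) -> Tensor:
        avg = f.mean(axis=(2, 3), keepdims=True)
        mx = f.max(3, keepdims=True).max(2, keepdims=True)
        gate = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return gate.sigmoid()

    def forward(self, f: Tensor) -> Tensor:
        return f * self.attention_weights(f)


class SPADE(Module):
    """Spatially-adaptive denormalization.

    The activations ``pf`` are instance-normalized (per-sample,
    per-channel mean/std over spatial positions) and re-modulated by
    spatially-varying scale and bias maps produced from previously
    extracted features ``PF`` through a shared conv + ReLU followed by
    one conv each for gamma and beta; ``PF`` is bilinearly resized to
    ``pf``'s spatial size first.
    """

    def __init__(self, channels: int, pf_channels: int, hidden: int = 64,
                 kernel: int = 3, eps: float = 1e-5,
                 rng: np.random.Generator | None = None):
        if eps <= 0:
            raise ValueError("eps must be > 0")
        pad = kernel // 2
        self.shared = Conv2d(pf_channels, hidden, kernel, padding=pad, rng=rng)
        self.gamma = Conv2d(hidden, channels, kernel, padding=pad, rng=rng)
        self.beta = Conv2d(hidden, channels, kernel, padding=pad, rng=rng)
        self.eps = eps

    def forward(self, pf: Tensor, PF: Tensor) -> Tensor:
        if pf.shape[0] != PF.shape[0]:
            raise ValueError(
                f"batch mismatch: pf {pf.shape[0]}, PF {PF.shape[0]}"
            )
        PF = resize_bilinear(PF, pf.shape[2:])
        h = self.shared(PF).relu()
        mu = pf.mean(axis=(2, 3), keepdims=True)
        var = ((pf - mu) ** 2).mean(axis=(2, 3), keepdims=True)
        sigma = (var + 1e-12).sqrt()
        normalized = (pf - mu) / (sigma + self.eps)
        return self.gamma(h) * normalized + self.beta(h)


def spade_denorm(pf: Tensor, PF: Tensor, modulation: SPADE, eps: float | None = None) -> Tensor:
    """Functional form of :class:`SPADE` (optionally overriding eps)."""
    if eps is not None:
        if eps <= 0:
            raise ValueError("eps must be > 0")
        modulation.eps = eps
    return modulation(pf, PF)


def spatial_attention(f: Tensor, gate: SpatialAttention) -> Tensor:
    return gate(f)


def channel_attention(f: Tensor, gate: ChannelAttention) -> Tensor:
    return gate(f)


class ResBlock(Module):
    """conv-IN-ReLU-conv-IN residual block with reflection padding."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(channels, channels, 3, padding=1, pad_mode="reflect", rng=rng)
        self.conv2 = Conv2d(channels, channels, 3, padding=1, pad_mode="reflect", rng=rng)
        self.norm1 = InstanceNorm2d()
        self.norm2 = InstanceNorm2d()

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return x + h


class AUEResBlock(Module):
    """Residual block whose normalizations are SPADE-modulated by encoder
    features, fusing the early ultrasound texture back in before decoding."""

    def __init__(self, channels: int, pf_channels: int,
                 rng: np.random.Generator | None = None):
        self.spade1 = SPADE(channels, pf_channels, rng=rng)
        self.spade2 = SPADE(channels, pf_channels, rng=rng)
        self.conv1 = Conv2d(channels, channels, 3, padding=1, pad_mode="reflect", rng=rng)
        self.conv2 = Conv2d(channels, channels, 3, padding=1, pad_mode="reflect", rng=rng)

    def forward(self, x: Tensor, pf_feats: Tensor) -> Tensor:
        h = self.conv1(self.spade1(x, pf_feats).relu())
        h = self.conv2(self.spade2(h, pf_feats).relu())
        return x + h


# ---------------------------------------------------------------------------
# generator


class Generator(Module):
    """B-mode (1 channel, [-1,1]) -> elastogram (3 channels, [-1,1])."""

    def __init__(self, config: GeneratorConfig | None = None):
        self.config = config = config or GeneratorConfig()
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        self.head = Sequential(
            Conv2d(config.in_channels, c, 7, padding=3, pad_mode="reflect", rng=rng),
            InstanceNorm2d(),
            ReLU(),
        )
        self.sa = SpatialAttention(rng=rng) if config.use_spatial_attention else None
        downs = []
        ch = c
        for _ in range(config.n_down):
            downs.append(
                Sequential(
                    Conv2d(ch, ch * 2, 3, stride=2, padding=1, pad_mode="reflect", rng=rng),
                    InstanceNorm2d(),
                    ReLU(),
                )
            )
            ch *= 2
        self.down_blocks = downs
        self.res_blocks = [ResBlock(ch, rng=rng) for _ in range(config.n_resblocks)]
        self.aue_resblock = (
            AUEResBlock(ch, ch, rng=rng) if config.use_aue_resblock else None
        )
        ups = []
        for _ in range(config.n_down):
            ups.append(
                Sequential(
                    Conv2d(ch, ch // 2, 3, padding=1, pad_mode="reflect", rng=rng),
                    InstanceNorm2d(),
                    ReLU(),
                )
            )
            ch //= 2
        self.up_blocks = ups
        self.ca = ChannelAttention(ch, rng=rng) if config.use_channel_attention else None
        self.tail = Sequential(
            Conv2d(ch, config.out_channels, 7, padding=3, pad_mode="reflect", rng=rng),
            Tanh(),
        )

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        div = 2 ** self.config.n_down
        if h % div or w % div:
            pad_h = (div - h % div) % div
            pad_w = (div - w % div) % div
            raise ValueError(
                f"input {h}x{w} not divisible by {div}; pad by "
                f"({pad_h}, {pad_w}) pixels"
            )
        f = self.head(x)
        if self.sa is not None:
            f = self.sa(f)
        for blk in self.down_blocks:
            f = blk(f)
        encoder_out = f
        for blk in self.res_blocks:
            f = blk(f)
        if self.aue_resblock is not None:
            f = self.aue_resblock(f, encoder_out)
        for blk in self.up_blocks:
            f = blk(upsample_nearest2d(f, 2))
        if self.ca is not None:
            f = self.ca(f)
        return self.tail(f)


def generator_forward(bmode: Tensor, config: GeneratorConfig | None = None,
                      generator: Generator | None = None) -> Tensor:
    """One generator pass (constructs a fresh seeded network if not given)."""
    gen = generator or Generator(config)
    return gen(bmode)


# ---------------------------------------------------------------------------
# discriminator


class PatchDiscriminator(Module):
    """Stride-2 conv stack emitting a grid of patch logits."""

    def __init__(self, config: DiscriminatorConfig, rng: np.random.Generator):
        conv = SpectralNormConv2d if config.spectral_norm else Conv2d
        slope = config.leaky_slope
        c = config.base_channels
        layers: list[Module] = [
            Sequential(conv(config.in_channels, c, 4, stride=2, padding=1, rng=rng),
                       LeakyReLU(slope))
        ]
        ch = c
        for _ in range(config.n_layers - 1):
            layers.append(
                Sequential(
                    conv(ch, min(ch * 2, 8 * c), 4, stride=2, padding=1, rng=rng),
                    InstanceNorm2d(),
                    LeakyReLU(slope),
                )
            )
            ch = min(ch * 2, 8 * c)
        self.blocks = layers
        self.score = conv(ch, 1, 4, stride=1, padding=1, rng=rng)

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        feats = []
        for blk in self.blocks:
            x = blk(x)
            feats.append(x)
        return self.score(x), feats


class MultiscaleDiscriminator(Module):
    """Patch discriminators applied at successively halved resolutions."""

    def __init__(self, config: DiscriminatorConfig | None = None):
        self.config = config = config or DiscriminatorConfig()
        rng = np.random.default_rng(config.seed)
        self.scales = [PatchDiscriminator(config, rng) for _ in range(config.n_scales)]

    def forward(self, condition: Tensor, candidate: Tensor
                ) -> tuple[list[Tensor], list[list[Tensor]]]:
        if condition.shape[2:] != candidate.shape[2:]:
            raise ValueError(
                f"condition {condition.shape[2:]} and candidate "
                f"{candidate.shape[2:]} spatial dims differ"
            )
        x = concat([condition, candidate], 1)
        logits, features = [], []
        for k, disc in enumerate(self.scales):
            if k > 0:
                x = avg_pool2d(x, 2)
            lg, ft = disc(x)
            logits.append(lg)
            features.append(ft)
        return logits, features


def discriminator_forward(condition: Tensor, candidate: Tensor,
                          config: DiscriminatorConfig | None = None,
                          discriminator: MultiscaleDiscriminator | None = None):
    disc = discriminator or MultiscaleDiscriminator(config)
    return disc(condition, candidate)
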