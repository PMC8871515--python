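"""scikit-learn style front end for AUE-net.

``AUENetTranslator`` is the package's central object: ``fit`` runs the
adversarial training loop on aligned (B-mode, elastogram) pairs and
``predict`` translates B-mode images into elastograms.  Module-level
training/inference helpers and the CLI are thin wrappers over it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .augment import AugmentConfig, augment_pair
from .losses import (
    BlurParams,
    LossWeights,
    color_loss,
    feature_matching_loss,
    gan_loss,
    perceptual_loss,
    total_generator_loss,
)
from .model import (
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
    MultiscaleDiscriminator,
)
from .nn import Adam, Tensor, no_grad
from .phantom import ImagePair

__all__ = ["AUENetTranslator"]


def _to_float(img: np.ndarray) -> np.ndarray:
    """uint8 [0,255] -> float32 [-1,1]."""
    return np.asarray(img, dtype=np.float32) / 127.5 - 1.0


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint((arr + 1.0) * 127.5), 0, 255).astype(np.uint8)


class AUENetTranslator(BaseEstimator):
    """Conditional-GAN translator from B-mode ultrasound to strain
    elastography.

    Parameters follow the reference training protocol: Adam with
    beta1=0.5, beta2=0.999 under two time-scale update rules
    (generator lr 2e-4, discriminator lr 1e-4), batch size 8, 1500
    epochs, feature-matching weight ``alpha`` and color-loss weight
    ``beta``.  Desk-scale runs override ``epochs``/``max_iterations``,
    ``batch_size`` and the channel widths.

    Parameters
    ----------
    base_channels, n_down, n_resblocks, use_* : generator architecture
        (3 down-sampling blocks, 9 residual blocks, 3 up-sampling blocks
        by default, plus the attention gates and the SPADE residual
        block).
    d_base_channels, n_scales, d_layers, spectral_norm : multiscale
        patch-discriminator architecture.
    alpha, beta, lambda_perceptual, gan_mode : loss weighting; the
        perceptual term is active only when ``perceptual_extractor`` is
        given.
    augment : AugmentConfig | bool
        Paired data augmentation (translation/flip/rotation); ``True``
        uses the defaults, ``False`` disables.
    random_state : int
        Seeds parameter init, batching, and augmentation.

    Attributes
    ----------
    generator_ : Generator
    discriminator_ : MultiscaleDiscriminator
    history_ : list of dict
        Per-iteration loss breakdown (keys: iteration, d_loss, gan,
        feature_matching, color, l1_monitor, total).
    n_iter_ : int
    """

    def __init__(
        self,
        base_channels: int = 64,
        n_down: int = 3,
        n_resblocks: int = 9,
        use_spatial_attention: bool = True,
        use_channel_attention: bool = True,
        use_aue_resblock: bool = True,
        d_base_channels: int = 64,
        n_scales: int = 2,
        d_layers: int = 3,
        spectral_norm: bool = True,
        epochs: int = 1500,
        max_iterations: int | None = None,
        batch_size: int = 8,
        lr_g: float = 0.0002,
        lr_d: float = 0.0001,
        beta1: float = 0.5,
        beta2: float = 0.999,
        alpha: float = 10.0,
        beta: float = 10.0,
        lambda_perceptual: float = 0.0,
        perceptual_extractor=None,
        gan_mode: str = "bce",
        blur_kernel: int = 21,
        blur_sigma: float = 3.0,
        augment=True,
        random_state: int = 0,
    ):
        self.base_channels = base_channels
        self.n_down = n_down
        self.n_resblocks = n_resblocks
        self.use_spatial_attention = use_spatial_attention
        self.use_channel_attention = use_channel_attention
        self.use_aue_resblock = use_aue_resblock
        self.d_base_channels = d_base_channels
        self.n_scales = n_scales
        self.d_layers = d_layers
        self.spectral_norm = spectral_norm
        self.epochs = epochs
        self.max_iterations = max_iterations
        self.batch_size = batch_size
        self.lr_g = lr_g
        self.lr_d = lr_d
        self.beta1 = beta1
        self.beta2 = beta2
        self.alpha = alpha
        self.beta = beta
        self.lambda_perceptual = lambda_perceptual
        self.perceptual_extractor = perceptual_extractor
        self.gan_mode = gan_mode
        self.blur_kernel = blur_kernel
        self.blur_sigma = blur_sigma
        self.augment = augment
        self.random_state = random_state

    # -- construction helpers ------------------------------------------------

    def _generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            base_channels=self.base_channels,
            n_down=self.n_down,
            n_resblocks=self.n_resblocks,
            use_spatial_attention=self.use_spatial_attention,
            use_channel_attention=self.use_channel_attention,
            use_aue_resblock=self.use_aue_resblock,
            seed=self.random_state,
        )

    def _discriminator_config(self) -> DiscriminatorConfig:
        return DiscriminatorConfig(
            base_channels=self.d_base_channels,
            n_scales=self.n_scales,
            n_layers=self.d_layers,
            spectral_norm=self.spectral_norm,
            seed=self.random_state + 1,
        )

    def _blur_params(self) -> BlurParams:
        return BlurParams((self.blur_kernel, self.blur_kernel), self.blur_sigma)

    def _loss_weights(self) -> LossWeights:
        return LossWeights(
            alpha=self.alpha,
            beta=self.beta,
            lambda_perceptual=self.lambda_perceptual,
            gan_mode=self.gan_mode,
        )

    def _augment_config(self) -> AugmentConfig | None:
        if self.augment is True:
            return AugmentConfig()
        if self.augment in (False, None):
            return None
        return self.augment

    @staticmethod
    def _as_arrays(X, Y=None) -> tuple[np.ndarray, np.ndarray | None]:
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError("X must be (n, H, W) grayscale images")
        if Y is None:
            return X, None
        Y = np.asarray(Y)
        if Y.ndim == 3:
            Y = Y[None]
        if Y.ndim != 4 or Y.shape[3] != 3:
            raise ValueError("Y must be (n, H, W, 3) RGB images")
        if X.shape[:3] != Y.shape[:3]:
            raise ValueError("X and Y must be aligned in count and size")
        return X, Y

    def _check_divisible(self, h: int, w: int) -> None:
        div = 2 ** self.n_down
        if h % div or w % div:
            raise ValueError(
                f"image size {h}x{w} must be divisible by {div} "
                f"(n_down={self.n_down})"
            )

    # -- training ------------------------------------------------------------

    def fit(self, X, Y, resume: bool = False):
        """Adversarial training on aligned pairs.

        ``X``: (n, H, W) uint8 B-mode images; ``Y``: (n, H, W, 3) uint8
        elastograms.  With ``resume=True`` and restored state (see
        :meth:`load_checkpoint`) training continues bit-compatibly from
        the stored iteration.
        """
        X, Y = self._as_arrays(X, Y)
        n = X.shape[0]
        if n == 0:
            raise ValueError("empty dataset")
        self._check_divisible(X.shape[1], X.shape[2])
        if not (resume and hasattr(self, "generator_")):
            self.generator_ = Generator(self._generator_config())
            self.discriminator_ = MultiscaleDiscriminator(self._discriminator_config())
            self._opt_g = Adam(self.generator_.parameters(), self.lr_g,
                               self.beta1, self.beta2)
            self._opt_d = Adam(self.discriminator_.parameters(), self.lr_d,
                               self.beta1, self.beta2)
            self._rng = np.random.default_rng(self.random_state)
            self.history_ = []
            self.n_iter_ = 0
        iters_per_epoch = max(n // self.batch_size, 1)
        total_iters = (
            self.max_iterations
            if self.max_iterations is not None
            else self.epochs * iters_per_epoch
        )
        aug_cfg = self._augment_config()
        blur = self._blur_params()
        weights = self._loss_weights()
        while self.n_iter_ < total_iters:
            idx = self._rng.integers(0, n, size=min(self.batch_size, n))
            xb, yb = [], []
            for i in idx:
                if aug_cfg is not None:
                    pair = augment_pair(
                        ImagePair(X[i], Y[i]), aug_cfg,
                        seed=int(self._rng.integers(0, 2**31)),
                    )
                    xb.append(pair.bmode)
                    yb.append(pair.elasto)
                else:
                    xb.append(X[i])
                    yb.append(Y[i])
            x = Tensor(_to_float(np.stack(xb))[:, None])
            y = Tensor(np.transpose(_to_float(np.stack(yb)), (0, 3, 1, 2)))
            record = self._train_step(x, y, blur, weights)
            record["iteration"] = self.n_iter_
            self.history_.append(record)
            self.n_iter_ += 1
        return self

    def _train_step(self, x: Tensor, y: Tensor, blur: BlurParams,
                    weights: LossWeights) -> dict:
        G, D = self.generator_, self.discriminator_

        fake = G(x)

        # discriminator update (generator output detached)
        D.zero_grad()
        logits_real, feats_real = D(x, y)
        logits_fake_d, _ = D(x, fake.detach())
        d_terms = [
            0.5 * (gan_loss(lr, True, weights.gan_mode)
                   + gan_loss(lf, False, weights.gan_mode))
            for lr, lf in zip(logits_real, logits_fake_d)
        ]
        d_loss = d_terms[0]
        for t in d_terms[1:]:
            d_loss = d_loss + t
        d_loss.backward()
        self._opt_d.step()

        # generator update (fresh discriminator pass through the graph;
        # real features recomputed so both sides see the updated D)
        G.zero_grad()
        D.zero_grad()
        with no_grad():
            _, feats_real = D(x, y)
        logits_fake, feats_fake = D(x, fake)
        gan_terms = [gan_loss(l, True, weights.gan_mode) for l in logits_fake]
        fm_terms = [
            feature_matching_loss([fr], [ff])
            for fr, ff in zip(feats_real, feats_fake)
        ]
        c_loss = color_loss((fake + 1.0) * 0.5, (y + 1.0) * 0.5, blur)
        p_term = None
        if self.perceptual_extractor is not None and weights.lambda_perceptual > 0:
            p_term = perceptual_loss(
                fake, y, self.perceptual_extractor, weights.perceptual_layer_weights
            )
        g_loss, breakdown = total_generator_loss(
            gan_terms, fm_terms, c_loss, weights, p_term
        )
        g_loss.backward()
        self._opt_g.step()

        breakdown["d_loss"] = float(d_loss.data)
        breakdown["l1_monitor"] = float(np.mean(np.abs(fake.data - y.data)))
        return breakdown

    # -- inference -----------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Deterministic translation of B-mode images into uint8 RGB
        elastograms (no noise input; repeated calls are bit-identical)."""
        if not hasattr(self, "generator_"):
            raise RuntimeError("estimator is not fitted")
        X, _ = self._as_arrays(X)
        div = 2 ** self.n_down
        outputs = []
        for i in range(X.shape[0]):
            img = X[i]
            h, w = img.shape
            ph = (div - h % div) % div
            pw = (div - w % div) % div
            if ph or pw:
                img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
            with no_grad():
                out = self.generator_(Tensor(_to_float(img)[None, None]))
            rgb = _to_uint8(np.transpose(out.data[0], (1, 2, 0)))
            outputs.append(rgb[:h, :w])
        return np.stack(outputs)

    # -- checkpointing -------------------------------------------------------

    def save_checkpoint(self, path: str | Path) -> None:
        """Weights + optimizer state + RNG state + config, resumable
        bit-compatibly on the same platform."""
        if not hasattr(self, "generator_"):
            raise RuntimeError("estimator is not fitted")
        path = Path(path)
        params = {k: v for k, v in self.get_params().items()
                  if k != "perceptual_extractor"}
        meta = {
            "params": params,
            "n_iter": self.n_iter_,
            "rng_state": self._rng.bit_generator.state,
            "history": self.history_,
        }
        arrays = {}
        for tag, state in (
            ("g", self.generator_.state_dict()),
            ("d", self.discriminator_.state_dict()),
        ):
            for k, v in state.items():
                arrays[f"{tag}::{k}"] = v
        for tag, opt in (("og", self._opt_g), ("od", self._opt_d)):
            st = opt.state_dict()
            arrays[f"{tag}::t"] = np.array(st["t"])
            for j, (m, v) in enumerate(zip(st["m"], st["v"])):
                arrays[f"{tag}::m{j}"] = m
                arrays[f"{tag}::v{j}"] = v
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load_checkpoint(cls, path: str | Path) -> "AUENetTranslator":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            est = cls(**meta["params"])
            est.generator_ = Generator(est._generator_config())
            est.discriminator_ = MultiscaleDiscriminator(est._discriminator_config())
            g_state = {k.split("::", 1)[1]: data[k] for k in data.files
                       if k.startswith("g::")}
            d_state = {k.split("::", 1)[1]: data[k] for k in data.files
                       if k.startswith("d::")}
            est.generator_.load_state_dict(g_state)
            est.discriminator_.load_state_dict(d_state)
            est._opt_g = Adam(est.generator_.parameters(), est.lr_g,
                              est.beta1, est.beta2)
            est._opt_d = Adam(est.discriminator_.parameters(), est.lr_d,
                              est.beta1, est.beta2)
            for tag, opt in (("og", est._opt_g), ("od", est._opt_d)):
                n_p = len(opt.params)
                opt.load_state_dict({
                    "t": int(data[f"{tag}::t"]),
                    "m": [data[f"{tag}::m{j}"] for j in range(n_p)],
                    "v": [data[f"{tag}::v{j}"] for j in range(n_p)],
                })
            est._rng = np.random.default_rng()
            est._rng.bit_generator.state = meta["rng_state"]
            est.history_ = meta["history"]
            est.n_iter_ = int(meta["n_iter"])
        return est
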