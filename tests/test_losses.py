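"""Loss functions against brute-force convolution oracles and closed forms."""

import numpy as np
import pytest

from aue.losses import (
    BlurParams,
    LossWeights,
    PERCEPTUAL_LAYER_WEIGHTS,
    RandomFeatureExtractor,
    color_loss,
    feature_matching_loss,
    gan_loss,
    gaussian_blur,
    gaussian_kernel,
    perceptual_loss,
    total_generator_loss,
)
from aue.nn import Tensor


def blur_loop_oracle(img, params):
    """Nested-loop reflect-padded convolution oracle."""
    kern = gaussian_kernel(params)
    k, l = params.kernel
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    padded = np.pad(arr, ((k // 2, k // 2), (l // 2, l // 2), (0, 0)), mode="reflect")
    h, w, c = arr.shape
    out = np.zeros_like(arr)
    for ch in range(c):
        for i in range(h):
            for j in range(w):
                acc = 0.0
                for a in range(k):
                    for b in range(l):
                        acc += padded[i + a, j + b, ch] * kern[a, b]
                out[i, j, ch] = acc
    return out[:, :, 0] if np.asarray(img).ndim == 2 else out


class TestGaussianBlur:
    def test_kernel_normalized_and_validated(self):
        assert gaussian_kernel(BlurParams((5, 7), 1.0)).sum() == pytest.approx(1.0)
        with pytest.raises(ValueError, match="odd"):
            BlurParams((4, 5), 1.0)
        with pytest.raises(ValueError, match="sigma"):
            BlurParams((5, 5), 0.0)

    def test_constant_image_unchanged(self):
        img = np.full((16, 16, 3), 42.0)
        out = gaussian_blur(img, BlurParams((5, 5), 1.5))
        np.testing.assert_allclose(out, 42.0, atol=1e-10)

    def test_impulse_reproduces_kernel(self):
        params = BlurParams((5, 5), 1.0)
        img = np.zeros((11, 11))
        img[5, 5] = 1.0
        out = gaussian_blur(img, params)
        np.testing.assert_allclose(out[3:8, 3:8], gaussian_kernel(params), atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        params = BlurParams((5, 3), 1.2)
        img = rng.uniform(0, 1, (16, 16, 3))
        np.testing.assert_allclose(
            gaussian_blur(img, params), blur_loop_oracle(img, params), atol=1e-6
        )

    def test_tensor_path_matches_numpy_path(self, rng):
        params = BlurParams((5, 5), 1.5)
        img = rng.uniform(0, 1, (6, 8, 3))
        want = gaussian_blur(img, params)
        t = Tensor(np.transpose(img, (2, 0, 1))[None].astype(np.float32))
        got = np.transpose(gaussian_blur(t, params).data[0], (1, 2, 0))
        assert np.max(np.abs(got - want)) < 1e-5


class TestColorLoss:
    def test_identity_is_zero(self, rng):
        x = rng.uniform(0, 1, (16, 16, 3))
        assert color_loss(x, x.copy()) == 0.0

    def test_uniform_offset_scores_two(self):
        x = np.full((16, 16, 3), 0.25)
        assert color_loss(x, x + 1.0) == pytest.approx(2.0, abs=1e-9)

    def test_symmetry(self, rng):
        x = rng.uniform(0, 1, (16, 16, 3))
        y = rng.uniform(0, 1, (16, 16, 3))
        assert color_loss(x, y) == pytest.approx(color_loss(y, x), abs=1e-12)

    def test_blurrable_texture_scores_below_global_shift(self):
        # 0/255 checkerboard vs mid-gray: blur averages the texture away,
        # so it must cost less than a full-range uniform shift
        params = BlurParams((21, 21), 5.0)
        idx = np.indices((32, 32)).sum(axis=0) % 2
        checker = np.repeat((idx * 255.0)[:, :, None], 3, axis=2)
        mid = np.full((32, 32, 3), 127.5)
        lo = color_loss(checker, mid, params)
        hi = color_loss(np.zeros((32, 32, 3)), np.full((32, 32, 3), 255.0), params)
        assert lo < hi

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            color_loss(np.zeros((8, 8, 3)), np.zeros((9, 8, 3)))


class TestGanLoss:
    def test_zero_logits_real_bce_is_ln2(self):
        assert gan_loss(np.zeros((2, 1, 4, 4)), True, "bce") == pytest.approx(
            np.log(2), abs=1e-6
        )

    def test_saturated_logits_drive_loss_to_zero(self):
        assert gan_loss(np.full((1, 1, 3, 3), 50.0), True, "bce") < 1e-6
        assert gan_loss(np.full((1, 1, 3, 3), -50.0), False, "bce") < 1e-6

    def test_lsgan_exact_target_is_zero(self):
        assert gan_loss(np.ones((1, 1, 2, 2)), True, "lsgan") == 0.0

    def test_unknown_mode_and_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            gan_loss(np.zeros((1, 1, 2, 2)), True, "wgan")
        with pytest.raises(ValueError, match="finite"):
            gan_loss(np.array([[np.inf]]), True, "bce")


class TestFeatureMatching:
    def test_identical_features_zero(self, rng):
        feats = [[Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))]]
        assert float(feature_matching_loss(feats, feats).data) == 0.0

    def test_constant_offset_gives_offset(self, rng):
        real = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
        fake = Tensor(real.data + 2.0)
        out = feature_matching_loss([[real]], [[fake]])
        assert float(out.data) == pytest.approx(2.0, abs=1e-6)

    def test_batch_replication_invariance(self, rng):
        a = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        b = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        one = feature_matching_loss([[Tensor(a)]], [[Tensor(b)]])
        two = feature_matching_loss(
            [[Tensor(np.repeat(a, 3, axis=0))]], [[Tensor(np.repeat(b, 3, axis=0))]]
        )
        assert float(one.data) == pytest.approx(float(two.data), abs=1e-6)

    def test_structure_mismatch_rejected(self, rng):
        f = [[Tensor(np.zeros((1, 2, 4, 4), np.float32))]]
        with pytest.raises(ValueError, match="scale"):
            feature_matching_loss(f, f + f)


class TestPerceptualLoss:
    def test_identity_zero_for_any_extractor(self, rng):
        ext = RandomFeatureExtractor(seed=4)
        x = Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32))
        assert float(perceptual_loss(x, x, ext).data) == 0.0

    def test_default_layer_weights(self):
        assert PERCEPTUAL_LAYER_WEIGHTS == (1 / 32, 1 / 16, 1 / 8, 1 / 4, 1.0)

    def test_linearity_in_layer_weights(self, rng):
        ext = RandomFeatureExtractor(seed=4)
        x = Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32))
        y = Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32))
        base = float(perceptual_loss(x, y, ext).data)
        doubled = float(
            perceptual_loss(x, y, ext, tuple(2 * w for w in PERCEPTUAL_LAYER_WEIGHTS)).data
        )
        assert doubled == pytest.approx(2 * base, rel=1e-5)

    def test_weight_count_mismatch_rejected(self, rng):
        ext = RandomFeatureExtractor(seed=4)
        x = Tensor(np.zeros((1, 3, 32, 32), np.float32))
        with pytest.raises(ValueError, match="weights"):
            perceptual_loss(x, x, ext, (1.0, 2.0))


class TestTotalLoss:
    def test_reduces_to_gan_sum_when_weights_zero(self):
        w = LossWeights(alpha=0.0, beta=0.0)
        total, breakdown = total_generator_loss([1.0, 2.5], [0.3, 0.4], 9.0, w)
        assert total == pytest.approx(3.5)
        assert breakdown["color"] == 0.0

    def test_documented_arithmetic_example(self):
        w = LossWeights(alpha=10.0, beta=1.0)
        total, _ = total_generator_loss([1.0, 2.0], [0.5, 0.5], 3.0, w)
        assert total == pytest.approx(16.0)

    def test_breakdown_sums_to_total(self, rng):
        w = LossWeights(alpha=7.0, beta=3.0)
        gan = list(rng.uniform(0, 2, 2))
        fm = list(rng.uniform(0, 2, 2))
        total, b = total_generator_loss(gan, fm, 1.7, w)
        assert b["gan"] + b["feature_matching"] + b["color"] == pytest.approx(
            total, abs=1e-9
        )

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-1.0)
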