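"""PSNR/SSIM/FID closed forms and oracles, and the color-dominance grade."""

import numpy as np
import pytest

from aue.metrics import (
    MetricReport,
    SSIMParams,
    evaluate_corpus,
    fid,
    grade_by_color_dominance,
    psnr,
    ssim,
)


def ssim_loop_oracle(i, g, p: SSIMParams):
    """Explicit sliding-window SSIM oracle (single channel)."""
    half = (p.window - 1) / 2
    ax = np.arange(p.window) - half
    k1d = np.exp(-0.5 * (ax / p.sigma) ** 2)
    kern = np.outer(k1d, k1d)
    kern /= kern.sum()
    c1 = (p.k1 * p.dynamic_range) ** 2
    c2 = (p.k2 * p.dynamic_range) ** 2
    h, w = i.shape
    n = p.window
    vals = []
    for r in range(h - n + 1):
        for c in range(w - n + 1):
            wi = i[r : r + n, c : c + n]
            wg = g[r : r + n, c : c + n]
            mi = (wi * kern).sum()
            mg = (wg * kern).sum()
            vi = (wi * wi * kern).sum() - mi * mi
            vg = (wg * wg * kern).sum() - mg * mg
            cov = (wi * wg * kern).sum() - mi * mg
            vals.append(
                ((2 * mi * mg + c1) * (2 * cov + c2))
                / ((mi**2 + mg**2 + c1) * (vi + vg + c2))
            )
    return float(np.mean(vals))


class TestPsnr:
    def test_identical_images_infinite(self, rng):
        img = rng.integers(0, 255, (16, 16, 3))
        assert psnr(img, img) == float("inf")

    def test_constant_offset_closed_form(self):
        i = np.full((32, 32, 3), 100.0)
        assert psnr(i, i + 16.0) == pytest.approx(
            10 * np.log10(255**2 / 256), abs=1e-6
        )
        assert psnr(i, i + 16.0) == pytest.approx(24.0489, abs=1e-3)

    def test_maximum_difference_is_zero_db(self):
        assert psnr(np.zeros((8, 8)), np.full((8, 8), 255.0)) == pytest.approx(0.0)

    def test_monotone_in_noise_amplitude(self, rng):
        img = rng.integers(60, 200, (32, 32)).astype(np.float64)
        noise = rng.uniform(-1, 1, img.shape)
        values = [psnr(img, img + a * noise) for a in (2.0, 6.0, 18.0)]
        assert values[0] > values[1] > values[2]


class TestSsim:
    def test_identical_images_exactly_one(self, rng):
        img = rng.integers(0, 255, (20, 20)).astype(np.float64)
        assert ssim(img, img) == 1.0

    def test_constant_extremes_closed_form(self):
        p = SSIMParams()
        c1 = (p.k1 * p.dynamic_range) ** 2
        want = c1 / (255.0**2 + c1)
        got = ssim(np.zeros((16, 16)), np.full((16, 16), 255.0), p)
        assert got == pytest.approx(want, rel=1e-9)
        assert got == pytest.approx(9.999e-5, rel=1e-3)

    def test_matches_sliding_window_oracle(self, rng):
        p = SSIMParams()
        i = rng.uniform(0, 255, (32, 32))
        g = rng.uniform(0, 255, (32, 32))
        assert ssim(i, g, p) == pytest.approx(ssim_loop_oracle(i, g, p), abs=1e-6)

    def test_agrees_with_skimage(self, rng):
        from skimage.metrics import structural_similarity

        i = rng.uniform(0, 255, (48, 48))
        g = i + rng.normal(0, 20, i.shape)
        ours = ssim(i, g)
        theirs = structural_similarity(
            i, g, gaussian_weights=True, sigma=1.5, data_range=255.0,
            use_sample_covariance=False,
        )
        assert ours == pytest.approx(theirs, abs=5e-3)

    def test_symmetry(self, rng):
        i = rng.uniform(0, 255, (24, 24))
        g = rng.uniform(0, 255, (24, 24))
        assert ssim(i, g) == pytest.approx(ssim(g, i), abs=1e-12)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestFid:
    def test_identical_feature_sets_zero(self, rng):
        a = rng.normal(size=(200, 6))
        assert fid(a, a) == pytest.approx(0.0, abs=1e-8)

    def test_one_dimensional_gaussian_closed_form(self, rng):
        # N(0,1) vs N(0,4): FID = (sigma1-sigma2)^2 = 1
        a = rng.normal(0.0, 1.0, (100_000, 1))
        b = rng.normal(0.0, 2.0, (100_000, 1))
        assert fid(a, b) == pytest.approx(1.0, abs=0.05)

    def test_mean_shift_closed_form(self, rng):
        a = rng.normal(size=(100_000, 4))
        b = rng.normal(size=(100_000, 4))
        b[:, 2] += 3.0
        assert fid(a, b) == pytest.approx(9.0, rel=0.05)

    def test_rotation_invariance(self, rng):
        from scipy.stats import ortho_group

        a = rng.normal(size=(500, 5))
        b = rng.normal(size=(500, 5)) + 0.3
        q = ortho_group.rvs(5, random_state=1)
        assert fid(a @ q, b @ q) == pytest.approx(fid(a, b), abs=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            fid(rng.normal(size=(10, 3)), rng.normal(size=(10, 4)))

    def test_warns_when_underdetermined(self, rng):
        with pytest.warns(UserWarning, match="singular"):
            fid(rng.normal(size=(4, 8)), rng.normal(size=(4, 8)))


def _nodule_image(nodule_rgb, ring_rgb, size=48, r=8):
    img = np.zeros((size, size, 3), np.uint8)
    img[:] = ring_rgb
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= r**2
    img[mask] = nodule_rgb
    return img, mask


class TestGrading:
    def test_green_nodule_is_grade_one(self):
        img, mask = _nodule_image((0, 255, 0), (0, 255, 0))
        assert grade_by_color_dominance(img, mask) == 1

    def test_blue_nodule_green_ring_grade_four(self):
        img, mask = _nodule_image((0, 0, 255), (0, 255, 0))
        assert grade_by_color_dominance(img, mask) == 4

    def test_blue_nodule_blue_ring_grade_five(self):
        img, mask = _nodule_image((0, 0, 255), (0, 0, 255))
        assert grade_by_color_dominance(img, mask) == 5

    def test_mixed_nodule_grades_two_and_three(self):
        img, mask = _nodule_image((0, 0, 255), (0, 255, 0))
        ys, xs = np.where(mask)
        blue_frac = 0.3
        n_green = int((1 - blue_frac) * len(ys))
        img[ys[:n_green], xs[:n_green]] = (0, 255, 0)
        assert grade_by_color_dominance(img, mask) == 2
        img[ys[: len(ys) // 4], xs[: len(ys) // 4]] = (0, 0, 255)
        assert grade_by_color_dominance(img, mask) == 3

    def test_brightness_scaling_invariance(self):
        img, mask = _nodule_image((0, 0, 200), (0, 200, 0))
        dimmed = (img.astype(np.float64) * 0.5).astype(np.uint8)
        assert grade_by_color_dominance(img, mask) == grade_by_color_dominance(
            dimmed, mask
        )

    def test_empty_and_border_touching_masks_rejected(self):
        img, mask = _nodule_image((0, 0, 255), (0, 255, 0))
        with pytest.raises(ValueError, match="empty"):
            grade_by_color_dominance(img, np.zeros_like(mask))
        bad = mask.copy()
        bad[0, :] = True
        with pytest.raises(ValueError, match="strictly inside"):
            grade_by_color_dominance(img, bad)


class TestEvaluateCorpus:
    def test_perfect_corpus(self, phantom_pairs):
        imgs = [p.elasto for p in phantom_pairs]
        masks = [p.mask for p in phantom_pairs]
        report = evaluate_corpus(imgs, [i.copy() for i in imgs], masks)
        assert all(v == float("inf") for v in report.psnr_values)
        assert report.ssim_mean == pytest.approx(1.0)
        assert report.fid == pytest.approx(0.0, abs=1e-6)
        assert report.grade_agreement == 1.0
        assert report.grade_matches == len(imgs)

    def test_single_pair_flags_undefined_std(self, phantom_pairs):
        p = phantom_pairs[0]
        report = evaluate_corpus([p.elasto], [p.bmode[..., None].repeat(3, axis=2)])
        assert report.n == 1
        assert report.ssim_std is None
        assert report.to_json()["ssim_std"] is None

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            evaluate_corpus([], [])
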