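"""Architecture contracts: SPADE denormalization vs a loop oracle,
attention gates, generator/discriminator shape and normalization
behavior."""

import numpy as np
import pytest

from aue.model import (
    SPADE,
    ChannelAttention,
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
    MultiscaleDiscriminator,
    SpatialAttention,
    spade_denorm,
)
from aue.nn import Tensor, no_grad


def spade_loop_oracle(pf, gamma, beta, eps=1e-5):
    """Per-sample, per-channel nested-loop normalization oracle."""
    out = np.zeros_like(pf)
    for n in range(pf.shape[0]):
        for c in range(pf.shape[1]):
            act = pf[n, c]
            mu = act.mean()
            sigma = act.std()
            out[n, c] = gamma[n, c] * (act - mu) / (sigma + eps) + beta[n, c]
    return out


def _force_identity_modulation(spade: SPADE):
    spade.shared.weight.data[:] = 0
    spade.shared.bias.data[:] = 0
    spade.gamma.weight.data[:] = 0
    spade.gamma.bias.data[:] = 1
    spade.beta.weight.data[:] = 0
    spade.beta.bias.data[:] = 0


class TestSpade:
    def test_identity_modulation_reduces_to_instance_norm(self, rng):
        spade = SPADE(3, 2, rng=rng)
        _force_identity_modulation(spade)
        pf = Tensor(rng.normal(size=(2, 3, 8, 8)).astype(np.float32))
        out = spade(pf, Tensor(rng.normal(size=(2, 2, 8, 8)).astype(np.float32))).data
        assert np.abs(out.mean(axis=(2, 3))).max() < 1e-4
        assert np.abs(out.std(axis=(2, 3)) - 1.0).max() < 1e-3

    def test_matches_loop_oracle_across_seeds(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            spade = SPADE(3, 2, hidden=4, rng=r)
            pf = r.normal(size=(2, 3, 4, 4)).astype(np.float32)
            mod = r.normal(size=(2, 2, 4, 4)).astype(np.float32)
            out = spade(Tensor(pf), Tensor(mod)).data
            with no_grad():
                h = spade.shared(Tensor(mod)).relu()
                gamma = spade.gamma(h).data
                beta = spade.beta(h).data
            want = spade_loop_oracle(
                pf.astype(np.float64), gamma.astype(np.float64),
                beta.astype(np.float64),
            )
            assert np.max(np.abs(out - want)) < 1e-5

    def test_constant_channel_gives_finite_beta_output(self, rng):
        spade = SPADE(2, 1, rng=rng)
        pf = Tensor(np.full((1, 2, 6, 6), 3.0, dtype=np.float32))
        mod = Tensor(rng.normal(size=(1, 1, 6, 6)).astype(np.float32))
        out = spade(pf, mod)
        assert np.isfinite(out.data).all()
        with no_grad():
            h = spade.shared(mod).relu()
            beta = spade.beta(h).data
        np.testing.assert_allclose(out.data, beta, atol=1e-5)

    def test_batch_mismatch_and_bad_eps_rejected(self, rng):
        spade = SPADE(2, 1, rng=rng)
        pf = Tensor(np.zeros((2, 2, 4, 4), np.float32))
        mod = Tensor(np.zeros((3, 1, 4, 4), np.float32))
        with pytest.raises(ValueError, match="batch"):
            spade(pf, mod)
        with pytest.raises(ValueError, match="eps"):
            spade_denorm(pf, Tensor(np.zeros((2, 1, 4, 4), np.float32)), spade, eps=0.0)

    def test_modulation_input_resized_to_activations(self, rng):
        spade = SPADE(2, 1, rng=rng)
        pf = Tensor(rng.normal(size=(1, 2, 8, 8)).astype(np.float32))
        mod = Tensor(rng.normal(size=(1, 1, 4, 4)).astype(np.float32))
        assert spade(pf, mod).shape == (1, 2, 8, 8)


class TestAttention:
    def test_spatial_gate_forced_open_is_identity(self, rng):
        sa = SpatialAttention(rng=rng)
        sa.conv.weight.data[:] = 0
        sa.conv.bias.data[:] = 100.0  # sigmoid -> ~1
        f = Tensor(rng.normal(size=(2, 5, 8, 8)).astype(np.float32))
        np.testing.assert_allclose(sa(f).data, f.data, atol=1e-4)

    def test_spatial_map_range_and_shape(self, rng):
        sa = SpatialAttention(rng=rng)
        f = Tensor(rng.normal(size=(2, 5, 8, 8)).astype(np.float32))
        a = sa.attention_map(f).data
        assert a.shape == (2, 1, 8, 8)
        assert (a > 0).all() and (a < 1).all()
        assert sa(f).shape == f.shape

    def test_spatial_attention_tracks_energy_blob(self, rng):
        sa = SpatialAttention(rng=rng)
        # mean-pool tap with positive weight: A follows channel-mean energy
        sa.conv.weight.data[:] = 0
        sa.conv.weight.data[0, 0, 3, 3] = 1.0
        sa.conv.bias.data[:] = 0
        f = np.zeros((1, 4, 16, 16), np.float32)
        f[0, :, 11, 5] = 50.0
        a = sa.attention_map(Tensor(f)).data[0, 0]
        assert np.unravel_index(a.argmax(), a.shape) == (11, 5)

    def test_channel_gate_forced_open_is_identity(self, rng):
        ca = ChannelAttention(8, rng=rng)
        ca.fc2.weight.data[:] = 0
        ca.fc2.bias.data[:] = 100.0
        f = Tensor(rng.normal(size=(2, 8, 6, 6)).astype(np.float32))
        np.testing.assert_allclose(ca(f).data, f.data, atol=1e-4)

    def test_channel_symmetry_for_duplicated_channels(self):
        rng = np.random.default_rng(0)
        ca = ChannelAttention(4, reduction=2, rng=rng)
        # symmetric initialization: identical rows/columns across channels
        ca.fc1.weight.data[:] = 0.1
        ca.fc1.bias.data[:] = 0.0
        ca.fc2.weight.data[:] = 0.1
        ca.fc2.bias.data[:] = 0.0
        f = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
        f[0, 2] = f[0, 1]  # duplicate channel
        w = ca.attention_weights(Tensor(f)).data[0, :, 0, 0]
        assert w[1] == pytest.approx(w[2], abs=1e-7)

    def test_channel_shape_preserved(self, rng):
        ca = ChannelAttention(64, rng=rng)
        f = Tensor(rng.normal(size=(2, 64, 16, 16)).astype(np.float32))
        assert ca(f).shape == (2, 64, 16, 16)


class TestGenerator:
    def test_output_shape_and_range(self, rng):
        g = Generator(GeneratorConfig(base_channels=8, seed=0))
        x = Tensor(rng.normal(size=(2, 1, 64, 64)).astype(np.float32))
        with no_grad():
            out = g(x)
        assert out.shape == (2, 3, 64, 64)
        assert out.data.min() >= -1.0 and out.data.max() <= 1.0

    def test_default_block_counts(self):
        g = Generator(GeneratorConfig())
        assert len(g.down_blocks) == 3
        assert len(g.res_blocks) == 9
        assert len(g.up_blocks) == 3
        assert g.aue_resblock is not None

    def test_indivisible_input_rejected_with_padding_hint(self, rng):
        g = Generator(GeneratorConfig(base_channels=8, seed=0))
        x = Tensor(rng.normal(size=(1, 1, 65, 65)).astype(np.float32))
        with pytest.raises(ValueError, match="pad"):
            g(x)

    def test_eval_forward_is_bit_identical(self, rng):
        g = Generator(GeneratorConfig(base_channels=8, seed=1))
        x = Tensor(rng.normal(size=(1, 1, 32, 32)).astype(np.float32))
        with no_grad():
            a = g(x).data
            b = g(x).data
        np.testing.assert_array_equal(a, b)

    def test_parameter_count_independent_of_input_size(self, rng):
        g = Generator(GeneratorConfig(base_channels=8, seed=1))
        n0 = g.n_parameters()
        with no_grad():
            g(Tensor(rng.normal(size=(1, 1, 32, 32)).astype(np.float32)))
            g(Tensor(rng.normal(size=(1, 1, 64, 64)).astype(np.float32)))
        assert g.n_parameters() == n0


class TestDiscriminator:
    def test_three_scales_strictly_decreasing_logit_maps(self, rng):
        d = MultiscaleDiscriminator(DiscriminatorConfig(base_channels=8, n_scales=3))
        x = Tensor(rng.normal(size=(1, 1, 64, 64)).astype(np.float32))
        y = Tensor(rng.normal(size=(1, 3, 64, 64)).astype(np.float32))
        with no_grad():
            logits, feats = d(x, y)
        sizes = [l.shape[2] for l in logits]
        assert len(logits) == 3
        assert sizes[0] > sizes[1] > sizes[2]
        assert all(len(f) == 3 for f in feats)

    def test_single_scale_degenerates_to_patch_discriminator(self, rng):
        d = MultiscaleDiscriminator(DiscriminatorConfig(base_channels=8, n_scales=1))
        x = Tensor(rng.normal(size=(1, 1, 32, 32)).astype(np.float32))
        y = Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32))
        with no_grad():
            logits, _ = d(x, y)
        assert len(logits) == 1
        assert logits[0].shape[1] == 1

    def test_spatial_mismatch_rejected(self, rng):
        d = MultiscaleDiscriminator(DiscriminatorConfig(base_channels=8))
        x = Tensor(np.zeros((1, 1, 32, 32), np.float32))
        y = Tensor(np.zeros((1, 3, 64, 64), np.float32))
        with pytest.raises(ValueError, match="spatial"):
            d(x, y)

    def test_all_conv_kernels_spectrally_bounded(self, rng):
        from aue.nn.modules import SpectralNormConv2d

        d = MultiscaleDiscriminator(DiscriminatorConfig(base_channels=8, seed=3))
        convs = [
            m for disc in d.scales
            for m in ([blk.layers[0] for blk in disc.blocks] + [disc.score])
        ]
        assert convs and all(isinstance(c, SpectralNormConv2d) for c in convs)
        for conv in convs:
            for _ in range(300):  # persistent power iteration converges
                conv._power_iterate()
            with no_grad():
                w = conv.normalized_weight().data
            sigma = np.linalg.svd(w.reshape(w.shape[0], -1), compute_uv=False)[0]
            assert sigma <= 1.0 + 1e-3
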