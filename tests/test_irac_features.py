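import numpy as np
import pytest

from leafwp import ACmixBlock, IRACConfig, build_irac, extract_features
from leafwp import nn


@pytest.fixture()
def block(rng):
    return ACmixBlock(channels=4, kernel=5, seq_len=12, n_heads=1, rng=rng)


class TestACmixBlock:
    def test_alpha_zero_reduces_to_conv_path(self, block, rng):
        x = nn.Tensor(rng.normal(size=(3, 4, 12)))
        block.alpha.data[...] = 0.0
        np.testing.assert_array_equal(block(x).data, block.conv_path(x).data)

    def test_beta_zero_reduces_to_attention_path(self, block, rng):
        x = nn.Tensor(rng.normal(size=(3, 4, 12)))
        block.beta.data[...] = 0.0
        np.testing.assert_array_equal(block(x).data, block.attention_path(x).data)

    def test_single_position_closed_form(self, rng):
        # with one position the attention weight collapses to 1, so the
        # block equals alpha * (value projection) + beta * (separable conv,
        # of which only the center depthwise tap touches the data)
        C, k = 3, 5
        b = ACmixBlock(channels=C, kernel=k, seq_len=1, n_heads=1, rng=rng)
        x = rng.normal(size=(2, C, 1))
        out = b(nn.Tensor(x)).data

        Wv = b.v_proj.weight.data[:, :, 0]
        bv = b.v_proj.bias.data
        att = np.einsum("oc,bc->bo", Wv, x[:, :, 0]) + bv

        Wpi = b.pw_in.weight.data[:, :, 0]
        bpi = b.pw_in.bias.data
        h = np.einsum("oc,bc->bo", Wpi, x[:, :, 0]) + bpi
        center = (k - 1) // 2
        h = h * b.dw.weight.data[:, center] + b.dw.bias.data
        Wpo = b.pw_out.weight.data[:, :, 0]
        bpo = b.pw_out.bias.data
        conv = np.einsum("oc,bc->bo", Wpo, h) + bpo

        expected = b.alpha.item() * att + b.beta.item() * conv
        np.testing.assert_allclose(out[:, :, 0], expected, atol=1e-6)

    def test_fusion_weights_receive_gradients(self, block, rng):
        x = nn.Tensor(rng.normal(size=(2, 4, 12)))
        loss = (block(x) ** 2.0).sum()
        loss.backward()
        assert block.alpha.grad is not None and abs(block.alpha.grad) > 0
        assert block.beta.grad is not None and abs(block.beta.grad) > 0

    def test_positional_table_shapes_attention(self, block, rng):
        x = nn.Tensor(rng.normal(size=(2, 4, 12)))
        base = block.attention_path(x).data.copy()
        # a constant shift along the softmax axis would be invisible; a
        # single-entry bump reweights one source position
        block.pos_table.data[0, 0, 0] += 3.0
        shifted = block.attention_path(x).data
        assert not np.allclose(base, shifted)

    def test_shape_mismatch_rejected(self, block, rng):
        with pytest.raises(ValueError):
            block(nn.Tensor(rng.normal(size=(2, 4, 9))))


class TestExtractor:
    def test_feature_length_and_batch_invariance(self, rng):
        cfg = IRACConfig(channels=4, seq_len=32)
        ext = build_irac(cfg, seed=3)
        X = rng.uniform(0, 1, size=(8, 32))
        batched = extract_features(ext, X)
        assert batched.shape == (8, cfg.feature_dim)
        singles = np.vstack([extract_features(ext, X[i : i + 1]) for i in range(8)])
        np.testing.assert_allclose(batched, singles, atol=1e-10)

    def test_identical_inputs_identical_features(self, rng):
        ext = build_irac(IRACConfig(channels=4, seq_len=32), seed=0)
        row = rng.uniform(0, 1, size=32)
        F = extract_features(ext, np.vstack([row, row]))
        np.testing.assert_array_equal(F[0], F[1])

    def test_zero_spectrum_finite(self):
        ext = build_irac(IRACConfig(channels=4, seq_len=32), seed=0)
        F = extract_features(ext, np.zeros((1, 32)))
        assert np.all(np.isfinite(F))

    def test_shifting_absorption_dip_changes_features(self, rng):
        cfg = IRACConfig(channels=4, seq_len=176)
        ext = build_irac(cfg, seed=1)
        base = np.full(176, 0.5)
        dip, shifted = base.copy(), base.copy()
        dip[60:70] = 0.1
        shifted[100:110] = 0.1
        f1 = extract_features(ext, dip[None, :])
        f2 = extract_features(ext, shifted[None, :])
        assert not np.allclose(f1, f2)

    def test_disabling_acmix_strictly_reduces_parameters(self):
        cfg = IRACConfig(channels=4, seq_len=32)
        with_acmix = build_irac(cfg, seed=0)
        baseline = build_irac(
            IRACConfig(channels=4, seq_len=32, acmix_enabled=False), seed=0
        )
        assert baseline.n_parameters() < with_acmix.n_parameters()

    def test_baseline_branches_are_plain_convolutions(self):
        ext = build_irac(IRACConfig(channels=4, seq_len=32, acmix_enabled=False), seed=0)
        assert not any(isinstance(b, ACmixBlock) for b in ext.branches)

    def test_band_count_mismatch_rejected(self, rng):
        ext = build_irac(IRACConfig(channels=4, seq_len=32), seed=0)
        with pytest.raises(ValueError):
            extract_features(ext, rng.uniform(size=(2, 33)))
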