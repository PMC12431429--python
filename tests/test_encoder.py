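"""Unimodal encoder: causal convolution, ConvSparseAttention, Transformer
with CLS token, Gaussian uncertainty head."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vigilnet._tensor import Tensor
from vigilnet.encoder import (ConvSparseAttention, EncoderConfig, TransformerEncoderWithCLS,
                              UncertaintyHead, UnimodalEncoder, default_encoder_configs)
from vigilnet.nn import Conv1d


def causal_conv_loop_oracle(x, weight, bias, kernel_size):
    """Explicit time-loop convolution with left zero padding."""
    B, C_in, S = x.shape
    k, g = kernel_size, weight.shape[1]
    C_out = weight.shape[1] * weight.shape[3]
    out = np.zeros((B, C_out, S))
    padded = np.concatenate([np.zeros((B, C_in, k - 1)), x], axis=2)
    cpg_in, cpg_out = C_in // g, C_out // g
    for b in range(B):
        for grp in range(g):
            for co in range(cpg_out):
                for t in range(S):
                    acc = 0.0
                    for j in range(k):
                        for ci in range(cpg_in):
                            acc += weight[j, grp, ci, co] * padded[b, grp * cpg_in + ci, t + j]
                    out[b, grp * cpg_out + co, t] = acc + bias[grp * cpg_out + co]
    return out


class TestCausalConv:
    def test_identity_kernel_passes_input_through(self, rng):
        conv = Conv1d(1, 1, 3, rng, padding_mode="causal")
        conv.weight.data[:] = 0.0
        conv.weight.data[2, 0, 0, 0] = 1.0  # current-time tap only
        conv.bias.data[:] = 0.0
        x = rng.normal(size=(2, 1, 9))
        out = conv(Tensor(x))
        assert np.allclose(out.data, x)

    def test_future_perturbation_never_changes_past_outputs(self, rng):
        conv = Conv1d(3, 5, 3, rng)
        x = rng.normal(size=(1, 3, 12))
        base = conv(Tensor(x)).data
        for t in range(11):
            perturbed = x.copy()
            perturbed[:, :, t + 1:] += rng.normal(size=perturbed[:, :, t + 1:].shape)
            out = conv(Tensor(perturbed)).data
            assert np.array_equal(out[:, :, :t + 1], base[:, :, :t + 1])

    def test_matches_explicit_loop_oracle(self, rng):
        conv = Conv1d(3, 4, 3, rng)
        x = rng.normal(size=(2, 3, 7))
        expected = causal_conv_loop_oracle(x, conv.weight.data, conv.bias.data, 3)
        assert np.allclose(conv(Tensor(x)).data, expected, atol=1e-12)

    def test_grouped_conv_matches_loop_oracle(self, rng):
        conv = Conv1d(4, 4, 3, rng, groups=4)  # depthwise
        x = rng.normal(size=(2, 4, 6))
        expected = causal_conv_loop_oracle(x, conv.weight.data, conv.bias.data, 3)
        assert np.allclose(conv(Tensor(x)).data, expected, atol=1e-12)

    def test_replicate_padding_matches_numpy_edge_pad(self, rng):
        conv = Conv1d(2, 3, 3, rng, padding_mode="replicate")
        x = rng.normal(size=(1, 2, 8))
        padded = np.pad(x, ((0, 0), (0, 0), (1, 1)), mode="edge")
        expected = np.zeros((1, 3, 8))
        for co in range(3):
            for t in range(8):
                expected[0, co, t] = sum(
                    conv.weight.data[j, 0, ci, co] * padded[0, ci, t + j]
                    for j in range(3) for ci in range(2)) + conv.bias.data[co]
        assert np.allclose(conv(Tensor(x)).data, expected, atol=1e-12)

    def test_empty_sequence_rejected(self, rng):
        conv = Conv1d(2, 2, 3, rng)
        with pytest.raises(ValueError):
            conv(Tensor(np.zeros((1, 2, 0))))


class TestConvSparseAttention:
    def test_output_shape_equals_input_shape(self, rng):
        csa = ConvSparseAttention(8, 4, rng)
        x = rng.normal(size=(3, 8, 5))
        csa.eval()
        assert csa(Tensor(x)).shape == x.shape

    def test_zeroed_attention_path_reduces_to_residual(self, rng):
        """With the attention branch silenced the elementwise product term
        vanishes and the block passes its input through unchanged."""
        csa = ConvSparseAttention(6, 2, rng)
        csa.eval()
        csa.attention.out_proj.weight.data[:] = 0.0
        csa.attention.out_proj.bias.data[:] = 0.0
        x = rng.normal(size=(2, 6, 4))
        assert np.allclose(csa(Tensor(x)).data, x, atol=1e-12)

    def test_eval_mode_forward_is_bitwise_reproducible(self, rng):
        csa = ConvSparseAttention(8, 4, rng)
        csa.eval()
        x = Tensor(rng.normal(size=(2, 8, 5)))
        assert np.array_equal(csa(x).data, csa(x).data)

    def test_head_count_falls_back_to_divisor(self, rng):
        csa = ConvSparseAttention(6, 4, rng)  # 4 does not divide 6
        assert csa.n_heads == 3


class TestTransformerWithCLS:
    def test_identical_rows_give_identical_cls_features(self, rng):
        enc = TransformerEncoderWithCLS(8, 4, 2, 16, 2, 0.0, rng)
        enc.eval()
        row = rng.normal(size=(1, 4, 8))
        x = np.concatenate([row, row], axis=0)
        cls = enc(Tensor(x)).data
        assert np.allclose(cls[0], cls[1], atol=1e-12)

    def test_zero_dropout_passes_are_identical(self, rng):
        enc = TransformerEncoderWithCLS(8, 3, 2, 16, 2, 0.0, rng)
        x = Tensor(rng.normal(size=(2, 3, 8)))
        enc.eval()
        assert np.array_equal(enc(x).data, enc(x).data)

    def test_published_cls_widths_per_modality(self, rng):
        """EEG encoders summarise to 64-d CLS features, EOG to 32-d."""
        configs = default_encoder_configs()
        for name, d in (("eeg2hz", 64), ("eog", 32), ("eeg5bands", 64)):
            enc = UnimodalEncoder(configs[name], rng)
            enc.eval()
            x = rng.normal(size=(2, configs[name].n_steps, configs[name].in_features))
            out = enc(x)
            assert out.cls_feature.shape == (2, d)
            assert out.mu.shape == (2,) and out.sigma2.shape == (2,)

    def test_empty_sequence_rejected(self, rng):
        enc = TransformerEncoderWithCLS(8, 3, 2, 16, 1, 0.0, rng)
        with pytest.raises(ValueError):
            enc(Tensor(np.zeros((1, 0, 8))))


class _UnitNoise:
    """Stub generator whose standard normal draws are all ones."""

    def standard_normal(self, shape):
        return np.ones(shape)

    def random(self, shape):  # pragma: no cover - dropout unused here
        return np.ones(shape)


class TestUncertaintyHead:
    def test_eval_mode_prediction_equals_mean(self, rng):
        head = UncertaintyHead(8, rng)
        head.eval()
        mu, sigma2, y_hat = head(Tensor(rng.normal(size=(4, 8))))
        assert np.array_equal(y_hat.data, mu.data)
        assert np.all(sigma2.data > 0)

    def test_variance_times_unit_noise_matches_printed_rule(self, rng):
        """mu 0.2, sigma^2 0.04, eps 1 -> sampled prediction 0.24 (the
        variance, not the standard deviation, multiplies the noise)."""
        head = UncertaintyHead(2, rng, noise_mode="var")
        head.mu_head.weight.data[:] = 0.0
        head.mu_head.bias.data[:] = 0.2
        head.logvar_head.weight.data[:] = 0.0
        head.logvar_head.bias.data[:] = np.log(0.04)
        head.training = True
        mu, sigma2, y_hat = head(Tensor(np.zeros((3, 2))), _UnitNoise())
        assert np.allclose(mu.data, 0.2)
        assert np.allclose(sigma2.data, 0.04)
        assert np.allclose(y_hat.data, 0.24)

    def test_std_noise_mode_uses_standard_deviation(self, rng):
        head = UncertaintyHead(2, rng, noise_mode="std")
        head.mu_head.weight.data[:] = 0.0
        head.mu_head.bias.data[:] = 0.2
        head.logvar_head.weight.data[:] = 0.0
        head.logvar_head.bias.data[:] = np.log(0.04)
        head.training = True
        _, _, y_hat = head(Tensor(np.zeros((1, 2))), _UnitNoise())
        assert np.allclose(y_hat.data, 0.2 + 0.2)

    def test_zeroed_variance_branch_gives_unit_variance(self, rng):
        head = UncertaintyHead(4, rng)
        head.logvar_head.weight.data[:] = 0.0
        head.logvar_head.bias.data[:] = 0.0
        head.eval()
        _, sigma2, _ = head(Tensor(rng.normal(size=(2, 4))))
        assert np.allclose(sigma2.data, 1.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_variance_is_always_positive(self, seed):
        r = np.random.default_rng(seed)
        head = UncertaintyHead(6, r)
        head.eval()
        _, sigma2, _ = head(Tensor(r.normal(scale=5.0, size=(8, 6))))
        assert np.all(sigma2.data > 0)


class TestEncoderPipeline:
    def test_conv_stack_is_causal_without_attention(self, tiny_encoder_config, rng):
        """Both conv layers with ConvSparseAttention bypassed: perturbing any
        future step leaves earlier outputs untouched (100 random trials)."""
        enc = UnimodalEncoder(tiny_encoder_config, rng)
        enc.eval()
        S = 10
        x = rng.normal(size=(1, tiny_encoder_config.in_features, S))
        base = enc.conv_stack(Tensor(x), use_attention=False).data
        for _ in range(100):
            t = rng.integers(0, S - 1)
            perturbed = x.copy()
            perturbed[:, :, t + 1:] += rng.normal(size=perturbed[:, :, t + 1:].shape)
            out = enc.conv_stack(Tensor(perturbed), use_attention=False).data
            assert np.array_equal(out[:, :, :t + 1], base[:, :, :t + 1])

    def test_input_shape_validation(self, tiny_encoder_config, rng):
        enc = UnimodalEncoder(tiny_encoder_config, rng)
        enc.eval()
        with pytest.raises(ValueError):
            enc(np.zeros((2, 5, 10)))  # wrong n_steps

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            EncoderConfig(in_features=10, n_steps=4, d_model=30, attn_heads=4,
                          conv2_channels=30)
        with pytest.raises(ValueError):
            EncoderConfig(in_features=10, n_steps=4, kernel_size=4)
        with pytest.raises(ValueError):
            EncoderConfig(in_features=10, n_steps=4, d_model=32, conv2_channels=64)

    def test_eval_forward_bitwise_reproducible(self, tiny_encoder_config, rng):
        enc = UnimodalEncoder(tiny_encoder_config, rng)
        enc.eval()
        x = rng.normal(size=(3, 4, 10))
        a, b = enc(x), enc(x)
        assert np.array_equal(a.mu.data, b.mu.data)
        assert np.array_equal(a.cls_feature.data, b.cls_feature.data)
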