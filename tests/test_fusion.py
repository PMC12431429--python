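"""Uncertainty-weighted cross-modal fusion: confidence weights, modulated
attention, multi-scale extractor, gating, residual branch."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vigilnet._tensor import Tensor
from vigilnet.encoder import UnimodalOutput
from vigilnet.fusion import FusionConfig, FusionModule, precision_weights


def small_config(**overrides):
    defaults = dict(d_model=8, n_heads=2, hidden1=4, hidden2=8, dropout=0.0,
                    attn_dropout=0.0)
    defaults.update(overrides)
    return FusionConfig(**defaults)


def make_outputs(rng, B=2, cls_dims=(8, 6, 8), sigma2=None):
    outs = []
    for i, d in enumerate(cls_dims):
        mu = Tensor(rng.normal(size=B))
        s2 = Tensor(sigma2[:, i] if sigma2 is not None else rng.uniform(0.1, 2.0, size=B))
        outs.append(UnimodalOutput(mu=mu, sigma2=s2, y_hat=mu,
                                   cls_feature=Tensor(rng.normal(size=(B, d)))))
    return outs


class TestPrecisionWeights:
    def test_equal_variances_give_uniform_weights(self):
        for v in (0.01, 1.0, 50.0):
            _, w = precision_weights(np.full((4, 3), v))
            assert np.allclose(w, 1.0 / 3.0)

    def test_hand_computed_case(self):
        """Variances (1, 1, 0.5) -> precisions (1, 1, 2) -> weights (0.25, 0.25, 0.5)."""
        pi, w = precision_weights(np.array([[1.0, 1.0, 0.5]]))
        assert np.allclose(pi, [[1.0, 1.0, 2.0]], rtol=1e-6)
        assert np.allclose(w, [[0.25, 0.25, 0.5]], rtol=1e-6)

    def test_vanishing_variance_dominates(self):
        _, w = precision_weights(np.array([[1e-12, 1.0, 1.0]]))
        assert w[0, 0] > 0.999999
        assert w[0, 1] < 1e-6 and w[0, 2] < 1e-6

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            precision_weights(np.array([[1.0, 0.0, 1.0]]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_weights_normalised_and_monotone(self, seed):
        r = np.random.default_rng(seed)
        s2 = r.uniform(0.01, 10.0, size=(5, 3))
        _, w = precision_weights(s2)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)
        # increasing one variance strictly decreases its weight
        bumped = s2.copy()
        bumped[:, 1] *= 2.0
        _, w2 = precision_weights(bumped)
        assert np.all(w2[:, 1] < w[:, 1])


def attention_loop_oracle(module: FusionModule, feats: np.ndarray, weights: np.ndarray):
    """Brute-force per-head, per-query reimplementation of the modulated
    cross-modal attention (normalised variant)."""
    cfg = module.config
    B, T, d = feats.shape
    h, dh = cfg.n_heads, cfg.head_dim

    def lin(layer, x):
        return x @ layer.weight.data + layer.bias.data

    fused = np.zeros((B, d))
    maps = np.zeros((B, h, T, T))
    for b in range(B):
        q = lin(module.q_proj, feats[b])
        k = lin(module.k_proj, feats[b])
        v = lin(module.v_proj, feats[b])
        conf_logits = (weights[b] @ module.conf_proj.weight.data
                       + module.conf_proj.bias.data).reshape(h, T)
        heads = []
        for head in range(h):
            sl = slice(head * dh, (head + 1) * dh)
            qs, ks, vs = q[:, sl], k[:, sl], v[:, sl]
            logits = cfg.beta * conf_logits[head]
            conf = np.exp(logits - logits.max())
            conf /= conf.sum()
            out_head = np.zeros((T, dh))
            for i in range(T):
                scores = np.array([qs[i] @ ks[j] / np.sqrt(dh) for j in range(T)])
                a = np.exp(scores - scores.max())
                a /= a.sum()
                a = a * conf
                a /= a.sum()
                maps[b, head, i] = a
                out_head[i] = sum(a[j] * vs[j] for j in range(T))
            heads.append(out_head)
        concat = np.concatenate(heads, axis=1)
        out = lin(module.out_proj, concat)
        fused[b] = out.mean(axis=0)
    return fused, maps


class TestCrossModalAttention:
    def test_matches_loop_oracle(self, rng):
        module = FusionModule(small_config(), [8, 6, 8], rng)
        module.eval()
        feats = rng.normal(size=(2, 3, 8))
        _, weights = precision_weights(rng.uniform(0.1, 2.0, size=(2, 3)))
        fused, maps = module.cross_modal_attention(Tensor(feats), Tensor(weights))
        oracle_fused, oracle_maps = attention_loop_oracle(module, feats, weights)
        assert np.allclose(fused.data, oracle_fused, atol=1e-6)
        assert np.allclose(maps.data, oracle_maps, atol=1e-6)

    def test_attention_rows_sum_to_one(self, rng):
        module = FusionModule(small_config(), [8, 6, 8], rng)
        module.eval()
        feats = rng.normal(size=(4, 3, 8))
        _, weights = precision_weights(rng.uniform(0.1, 2.0, size=(4, 3)))
        _, maps = module.cross_modal_attention(Tensor(feats), Tensor(weights))
        assert np.allclose(maps.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_identical_features_and_uniform_weights_are_symmetric(self, rng):
        """With all three modality tokens equal, attention output is the
        same regardless of how attention distributes over the keys."""
        module = FusionModule(small_config(), [8, 6, 8], rng)
        module.eval()
        token = rng.normal(size=(1, 1, 8))
        feats = np.repeat(token, 3, axis=1)
        weights = np.full((1, 3), 1.0 / 3.0)
        fused, _ = module.cross_modal_attention(Tensor(feats), Tensor(weights))
        v = token[0] @ module.v_proj.weight.data + module.v_proj.bias.data
        expected = v @ module.out_proj.weight.data + module.out_proj.bias.data
        assert np.allclose(fused.data, expected, atol=1e-10)

    def test_literal_variant_multiplies_raw_scores(self, rng):
        module = FusionModule(small_config(attention_variant="literal"), [8, 6, 8], rng)
        module.eval()
        feats = rng.normal(size=(2, 3, 8))
        _, weights = precision_weights(rng.uniform(0.1, 2.0, size=(2, 3)))
        _, maps = module.cross_modal_attention(Tensor(feats), Tensor(weights))
        # raw modulated scores are not row-normalised
        assert not np.allclose(maps.data.sum(axis=-1), 1.0)


class TestMultiscaleAndGate:
    def test_multiscale_output_width(self, rng):
        module = FusionModule(small_config(), [8, 6, 8], rng)
        module.eval()
        out = module.multiscale_extract(Tensor(rng.normal(size=(5, 6))))
        assert out.shape == (5, 8)

    def test_multiscale_zero_parameters_give_zero_output(self, rng):
        module = FusionModule(small_config(), [8, 6, 8], rng)
        module.eval()
        for layer in (module.ms_lin1, module.ms_lin2):
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0
        module.ms_norm.bias.data[:] = 0.0
        out = module.multiscale_extract(Tensor(rng.normal(size=(3, 6))))
        assert np.allclose(out.data, 0.0)

    def test_multiscale_rejects_wrong_width(self, rng):
        module = FusionModule(small_config(), [8, 6, 8], rng)
        with pytest.raises(ValueError):
            module.multiscale_extract(Tensor(np.zeros((2, 5))))

    def test_zeroed_gate_parameters_give_half_gate(self, rng):
        module = FusionModule(small_config(), [8, 6, 8], rng)
        module.eval()
        for layer in (module.gate_lin1, module.gate_lin2):
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0
        feature = rng.normal(size=(3, 8))
        gate, g_final = module.gate_fuse(Tensor(rng.normal(size=(3, 8))), Tensor(feature))
        assert np.allclose(gate.data, 0.5)
        assert np.allclose(g_final.data, 0.5 * feature)

    def test_saturated_gate_is_identity(self, rng):
        module = FusionModule(small_config(), [8, 6, 8], rng)
        module.eval()
        module.gate_lin2.weight.data[:] = 0.0
        module.gate_lin2.bias.data[:] = 50.0
        feature = rng.normal(size=(2, 8))
        _, g_final = module.gate_fuse(Tensor(rng.normal(size=(2, 8))), Tensor(feature))
        assert np.allclose(g_final.data, feature, atol=1e-12)

    def test_zero_feature_absorbs_any_gate(self, rng):
        module = FusionModule(small_config(), [8, 6, 8], rng)
        module.eval()
        _, g_final = module.gate_fuse(Tensor(rng.normal(size=(2, 8))),
                                      Tensor(np.zeros((2, 8))))
        assert np.allclose(g_final.data, 0.0)


class TestResidualBranch:
    def test_zero_parameters_give_zero_prediction(self, rng):
        module = FusionModule(small_config(), [8, 6, 8], rng)
        for layer in (module.res_lin1, module.res_lin2):
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0
        module.res_norm.bias.data[:] = 0.0
        out = module.residual_branch(Tensor(rng.normal(size=(4, 6))))
        assert np.allclose(out.data, 0.0)

    def test_matches_hand_computed_two_layer_evaluation(self, rng):
        module = FusionModule(small_config(), [8, 6, 8], rng)
        x = rng.normal(size=(3, 6))
        h = np.maximum(x @ module.res_lin1.weight.data + module.res_lin1.bias.data, 0.0)
        mu = h.mean(axis=-1, keepdims=True)
        var = ((h - mu) ** 2).mean(axis=-1, keepdims=True)
        normed = (h - mu) / np.sqrt(var + module.res_norm.eps)
        normed = normed * module.res_norm.weight.data + module.res_norm.bias.data
        expected = (normed @ module.res_lin2.weight.data + module.res_lin2.bias.data)
        out = module.residual_branch(Tensor(x))
        assert out.shape == (3,)
        assert np.allclose(out.data, expected.reshape(-1), atol=1e-10)


class TestFullFusionForward:
    def test_weights_sum_to_one_and_gate_in_unit_interval(self, rng):
        module = FusionModule(small_config(), [8, 6, 8], rng)
        module.eval()
        state = module(make_outputs(rng, B=6))
        assert np.allclose(state.weights.data.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((state.gate.data > 0.0) & (state.gate.data < 1.0))

    def test_final_prediction_is_exact_branch_sum(self, rng):
        module = FusionModule(small_config(), [8, 6, 8], rng)
        module.eval()
        state = module(make_outputs(rng, B=5))
        assert np.array_equal(state.y_fusion.data,
                              state.y_fused.data + state.y_residual.data)

    def test_zero_residual_parameters_make_fusion_equal_fused(self, rng):
        module = FusionModule(small_config(), [8, 6, 8], rng)
        module.eval()
        for layer in (module.res_lin1, module.res_lin2):
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0
        module.res_norm.bias.data[:] = 0.0
        state = module(make_outputs(rng, B=4))
        assert np.allclose(state.y_fusion.data, state.y_fused.data)

    def test_x_fusion_stacks_predictions_then_variances(self, rng):
        module = FusionModule(small_config(), [8, 6, 8], rng)
        module.eval()
        outs = make_outputs(rng, B=3)
        state = module(outs)
        expected = np.stack([o.y_hat.data for o in outs]
                            + [o.sigma2.data for o in outs], axis=1)
        assert np.array_equal(state.x_fusion.data, expected)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            FusionConfig(d_model=8, n_heads=3, hidden2=8)
        with pytest.raises(ValueError):
            FusionConfig(d_model=8, n_heads=2, hidden2=16)
        with pytest.raises(ValueError):
            FusionConfig(beta=0.0)

    def test_requires_exactly_three_modalities(self, rng):
        with pytest.raises(ValueError):
            FusionModule(small_config(), [8, 6], rng)
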