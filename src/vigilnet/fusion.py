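"""Uncertainty-weighted cross-modal fusion.

The three modality encoders hand over their CLS features, sampled
predictions and predictive variances.  Fusion then:

1. projects every CLS feature into a shared ``d_model`` space and stacks
   them into a 3-token sequence;
2. converts the variances to precisions ``pi_i = 1/(sigma_i^2 + eps)`` and
   normalised confidence weights ``w_i = pi_i / sum_j pi_j``;
3. runs multi-head attention over the 3 modality tokens whose row-softmaxed
   scores are modulated along the key axis by a learned projection of the
   confidence weights (softmax of ``beta`` times the projected logits), then
   renormalised — so high-confidence modalities receive more attention.  The
   head outputs are concatenated, output-projected and averaged over the
   modality positions into ``feature_fused``;
4. feeds the 6-vector ``[y1, y2, y3, s1, s2, s3]`` through a multi-scale
   extractor (6 -> 32 -> LayerNorm -> 64 -> dropout), gates ``feature_fused``
   with a two-layer sigmoid MLP over the concatenation of both streams, and
   produces the final prediction as the sum of a fused branch (on the gated
   feature) and a residual branch (directly on the 6-vector).

Confidence weights entering the attention modulation are treated as
constants under differentiation, so the network cannot lower its loss by
inflating a modality's variance; variances are trained through the
negative-log-likelihood objective only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, cat, stack
from .encoder import UnimodalOutput
from .nn import Dropout, LayerNorm, Linear, Module, softmax

__all__ = ["FusionConfig", "FusionState", "precision_weights", "FusionModule"]


@dataclass(frozen=True)
class FusionConfig:
    d_model: int = 64
    n_heads: int = 4
    beta: float = 0.5           # scaling of confidence logits in the score modulation
    attn_dropout: float = 0.1
    dropout: float = 0.3
    epsilon: float = 1e-8
    hidden1: int = 32
    hidden2: int = 64
    attention_variant: str = "normalized"   # or "literal" (raw scores times values)
    stop_gradient_weights: bool = True

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.hidden2 != self.d_model:
            raise ValueError("hidden2 must equal d_model (gate input is their concat)")
        if self.attention_variant not in ("normalized", "literal"):
            raise ValueError("attention_variant must be 'normalized' or 'literal'")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class FusionState:
    """Intermediates of one fusion forward pass (autodiff tensors)."""

    features: Tensor        # [B, 3, d_model] projected, stacked
    precision: Tensor       # [B, 3]
    weights: Tensor         # [B, 3], rows sum to 1
    attn_maps: Tensor       # [B, n_heads, 3, 3]
    feature_fused: Tensor   # [B, d_model]
    x_fusion: Tensor        # [B, 6]
    x_enhanced: Tensor      # [B, hidden2]
    gate: Tensor            # [B, d_model], in (0, 1)
    g_final: Tensor         # [B, d_model]
    y_fused: Tensor         # [B]
    y_residual: Tensor      # [B]
    y_fusion: Tensor        # [B]


def precision_weights(sigma2: np.ndarray, epsilon: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Precisions and normalised confidence weights from variances ``[B, 3]``.

    ``pi_i = 1 / (sigma_i^2 + eps)``; ``w_i = pi_i / sum_j pi_j``.  Weights
    sum to one per sample and decrease strictly in the own variance.
    """
    sigma2 = np.asarray(sigma2, dtype=np.float64)
    if np.any(sigma2 <= 0):
        raise ValueError("variances must be strictly positive")
    precision = 1.0 / (sigma2 + epsilon)
    weights = precision / precision.sum(axis=-1, keepdims=True)
    return precision, weights


class FusionModule(Module):
    """Cross-modal fusion over exactly three modality encoders."""

    def __init__(self, config: FusionConfig, cls_dims: list[int], rng: np.random.Generator):
        super().__init__()
        if len(cls_dims) != 3:
            raise ValueError("fusion is defined for exactly three modalities")
        self.config = config
        d = config.d_model
        self.projections = [Linear(dim, d, rng) for dim in cls_dims]
        self.q_proj = Linear(d, d, rng)
        self.k_proj = Linear(d, d, rng)
        self.v_proj = Linear(d, d, rng)
        self.out_proj = Linear(d, d, rng)
        self.conf_proj = Linear(3, config.n_heads * 3, rng)   # confidence -> per-head key logits
        self.attn_drop = Dropout(config.attn_dropout)
        # multi-scale extractor: 6 -> 32 -> LayerNorm -> 64 -> dropout
        self.ms_lin1 = Linear(6, config.hidden1, rng)
        self.ms_norm = LayerNorm(config.hidden1)
        self.ms_lin2 = Linear(config.hidden1, config.hidden2, rng)
        self.ms_drop = Dropout(config.dropout)
        # gate: [x_enhanced, feature_fused] (2d) -> d -> d, sigmoid
        self.gate_lin1 = Linear(2 * d, d, rng)
        self.gate_lin2 = Linear(d, d, rng)
        # fused branch: d -> 32 -> 1
        self.fused_lin1 = Linear(d, config.hidden1, rng)
        self.fused_drop = Dropout(config.dropout)
        self.fused_lin2 = Linear(config.hidden1, 1, rng)
        # residual branch: 6 -> 32 -> LayerNorm -> 1
        self.res_lin1 = Linear(6, config.hidden1, rng)
        self.res_norm = LayerNorm(config.hidden1)
        self.res_lin2 = Linear(config.hidden1, 1, rng)
        # ablation switches (toggled by apply_ablation)
        self.use_cross_modal_attention = True
        self.use_multiscale = True
        self.use_uncertainty_weighting = True

    # -- pieces ---------------------------------------------------------------

    def _confidence(self, sigma2: Tensor) -> tuple[Tensor, Tensor]:
        cfg = self.config
        if self.use_uncertainty_weighting:
            s2 = sigma2.detach() if cfg.stop_gradient_weights else sigma2
            precision = 1.0 / (s2 + cfg.epsilon)
            weights = precision / precision.sum(axis=-1, keepdims=True)
        else:
            precision = Tensor(np.full(sigma2.shape, 3.0))
            weights = Tensor(np.full(sigma2.shape, 1.0 / 3.0))
        return precision, weights

    def cross_modal_attention(self, features: Tensor, weights: Tensor,
                              rng: np.random.Generator | None = None
                              ) -> tuple[Tensor, Tensor]:
        """Confidence-modulated attention over the 3 modality tokens.

        Returns ``(feature_fused [B, d_model], attn_maps [B, n_heads, 3, 3])``.
        """
        cfg = self.config
        B, T, d = features.shape
        h, dh = cfg.n_heads, cfg.head_dim

        def split(x):
            return x.reshape(B, T, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.q_proj(features)), split(self.k_proj(features)), \
            split(self.v_proj(features))
        scores = (q @ k.transpose(0, 1, 3, 2)) / math.sqrt(dh)    # [B, h, T, T]
        conf = softmax(self.conf_proj(weights).reshape(B, h, 1, T) * cfg.beta, axis=-1)
        if cfg.attention_variant == "normalized":
            attn = softmax(scores, axis=-1) * conf
            attn = attn / attn.sum(axis=-1, keepdims=True)
        else:  # literal: raw scaled scores times the confidence softmax
            attn = scores * conf
        out = self.attn_drop(attn, rng) @ v                       # [B, h, T, dh]
        out = out.transpose(0, 2, 1, 3).reshape(B, T, d)
        out = self.out_proj(out)
        feature_fused = out.mean(axis=1)                          # average over modalities
        return feature_fused, attn

    def multiscale_extract(self, x_fusion: Tensor,
                           rng: np.random.Generator | None = None) -> Tensor:
        if x_fusion.shape[-1] != 6:
            raise ValueError("x_fusion must have width 6")
        h = self.ms_norm(self.ms_lin1(x_fusion))
        return self.ms_drop(self.ms_lin2(h), rng)

    def gate_fuse(self, x_enhanced: Tensor, feature_fused: Tensor) -> tuple[Tensor, Tensor]:
        gate_in = cat([x_enhanced, feature_fused], axis=-1)
        if gate_in.shape[-1] != 2 * self.config.d_model:
            raise ValueError("gate input width must be 2 * d_model")
        gate = self.gate_lin2(self.gate_lin1(gate_in).relu()).sigmoid()
        return gate, gate * feature_fused

    def residual_branch(self, x_fusion: Tensor) -> Tensor:
        if x_fusion.shape[-1] != 6:
            raise ValueError("x_fusion must have width 6")
        h = self.res_norm(self.res_lin1(x_fusion).relu())
        return self.res_lin2(h).reshape(-1)

    def fused_branch(self, g_final: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        h = self.fused_drop(self.fused_lin1(g_final).relu(), rng)
        return self.fused_lin2(h).reshape(-1)

    # -- full forward ---------------------------------------------------------

    def forward(self, outputs: list[UnimodalOutput],
                rng: np.random.Generator | None = None) -> FusionState:
        if len(outputs) != 3:
            raise ValueError("fusion expects exactly three unimodal outputs")
        features = stack([proj(o.cls_feature) for proj, o in zip(self.projections, outputs)],
                         axis=1)                                   # [B, 3, d]
        sigma2 = stack([o.sigma2 for o in outputs], axis=1)        # [B, 3]
        precision, weights = self._confidence(sigma2)

        if self.use_cross_modal_attention:
            feature_fused, attn_maps = self.cross_modal_attention(features, weights, rng)
        else:
            feature_fused = features.mean(axis=1)
            attn_maps = Tensor(np.full(
                (features.shape[0], self.config.n_heads, 3, 3), 1.0 / 3.0))

        x_fusion = stack([o.y_hat for o in outputs] + [o.sigma2 for o in outputs],
                         axis=1)                                   # [B, 6]
        if self.use_multiscale:
            x_enhanced = self.multiscale_extract(x_fusion, rng)
        else:
            pad = Tensor(np.zeros((x_fusion.shape[0], self.config.hidden2 - 6)))
            x_enhanced = cat([x_fusion, pad], axis=-1)

        gate, g_final = self.gate_fuse(x_enhanced, feature_fused)
        y_fused = self.fused_branch(g_final, rng)
        y_residual = self.residual_branch(x_fusion)
        y_fusion = y_fused + y_residual
        return FusionState(features=features, precision=precision, weights=weights,
                           attn_maps=attn_maps, feature_fused=feature_fused,
                           x_fusion=x_fusion, x_enhanced=x_enhanced, gate=gate,
                           g_final=g_final, y_fused=y_fused, y_residual=y_residual,
                           y_fusion=y_fusion)
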