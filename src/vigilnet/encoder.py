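"""Per-modality feature extractor with a heteroscedastic Gaussian head.

Each modality arrives as ``[B, n_steps, n_features]`` — for EEG, four
feature-type rows (PSD/DE, each moving-average and LDS smoothed) over the
flattened channel-frequency axis.  The encoder permutes this to
``[B, n_features, n_steps]`` and applies, in order:

1. two causal 1-D convolutions (features -> 16 -> 64/32 channels), each
   followed by ReLU and a ConvSparseAttention block;
2. a Transformer encoder over the step axis with a learned CLS token and
   positional embeddings, whose CLS output summarises the sample;
3. two linear heads on the CLS feature: the predictive mean, and the log of
   the predictive variance (exponentiated, so the variance is always
   positive).  In training mode the sampled prediction is
   ``mu + sigma^2 * eps`` with standard-normal ``eps`` (a documented
   ``noise_mode="std"`` switch uses ``mu + sigma * eps`` instead); in
   evaluation mode the sampled prediction equals the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._tensor import Parameter, Tensor, cat
from .nn import (BatchNorm1d, Conv1d, Dropout, LayerNorm, Linear,
                 Module, MultiheadAttention)

__all__ = [
    "EncoderConfig",
    "UnimodalOutput",
    "default_encoder_configs",
    "ConvSparseAttention",
    "TransformerEncoderWithCLS",
    "UncertaintyHead",
    "UnimodalEncoder",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of one modality's encoder.

    ``n_steps`` is the sequence length seen by the convolutions and the
    Transformer (the 4/4/3 feature-type rows of a sample); ``in_features``
    is the flattened channel-frequency width (425/36/85) treated as the
    convolution's input channels.
    """

    in_features: int
    n_steps: int
    conv1_channels: int = 16
    conv2_channels: int = 64
    kernel_size: int = 3
    attn_heads: int = 4
    d_model: int = 64
    ffn_dim: int = 128
    n_layers: int = 2
    dropout: float = 0.3
    padding_mode: str = "causal"      # or "replicate"
    noise_mode: str = "var"           # sampled prediction: mu + sigma^2*eps ("std": sigma*eps)
    use_conv_sparse_attention: bool = True

    def __post_init__(self):
        if self.d_model % self.attn_heads:
            raise ValueError("d_model must be divisible by attn_heads")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.d_model != self.conv2_channels:
            raise ValueError("d_model must equal conv2_channels (tokens come from conv2)")
        if self.noise_mode not in ("var", "std"):
            raise ValueError("noise_mode must be 'var' or 'std'")


def default_encoder_configs() -> dict[str, EncoderConfig]:
    """Default encoder configurations for the three modalities."""
    return {
        "eeg2hz": EncoderConfig(in_features=425, n_steps=4, conv2_channels=64, d_model=64),
        "eog": EncoderConfig(in_features=36, n_steps=3, conv2_channels=32, d_model=32),
        "eeg5bands": EncoderConfig(in_features=85, n_steps=4, conv2_channels=64, d_model=64),
    }


@dataclass
class UnimodalOutput:
    """Per-sample outputs of one modality encoder (autodiff tensors)."""

    mu: Tensor          # [B]
    sigma2: Tensor      # [B], always > 0
    y_hat: Tensor       # [B]; equals mu in evaluation mode
    cls_feature: Tensor  # [B, d_model]


def _attention_heads_for(channels: int, requested: int) -> int:
    """Largest head count <= requested that divides the channel width."""
    for h in range(min(requested, channels), 0, -1):
        if channels % h == 0:
            return h
    return 1


class ConvSparseAttention(Module):
    """Convolutional attention block applied after each conv layer.

    Four parallel/sequential steps on ``[B, C, S]`` input:

    1. a kernel-1 convolution compresses the channels to one map, which is
       expanded back to ``C`` channels;
    2. depthwise (groups = C) then pointwise convolution with ReLU;
    3. the result, transposed to ``[B, S, C]``, goes through softmax-
       normalised multi-head attention, giving attention-weighted features;
    4. a parallel conv -> batch-norm -> ReLU path on the original input is
       multiplied elementwise with the attention-weighted features, and the
       original input is added back (residual).  Output shape = input shape.
    """

    def __init__(self, channels: int, attn_heads: int, rng: np.random.Generator,
                 kernel_size: int = 3, padding_mode: str = "causal"):
        super().__init__()
        self.channels = channels
        self.n_heads = _attention_heads_for(channels, attn_heads)
        self.compress = Conv1d(channels, 1, 1, rng)
        self.depthwise = Conv1d(channels, channels, kernel_size, rng,
                                padding_mode=padding_mode, groups=channels)
        self.pointwise = Conv1d(channels, channels, 1, rng)
        self.attention = MultiheadAttention(channels, self.n_heads, rng)
        self.parallel_conv = Conv1d(channels, channels, kernel_size, rng,
                                    padding_mode=padding_mode)
        self.parallel_bn = BatchNorm1d(channels)

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        B, C, S = x.shape
        compressed = self.compress(x)                       # [B, 1, S]
        expanded = compressed * Tensor(np.ones((1, C, 1)))  # repeat to [B, C, S]
        local = self.pointwise(self.depthwise(expanded)).relu()
        attended = self.attention(local.swapaxes(1, 2), rng)  # [B, S, C]
        attended = attended.swapaxes(1, 2)                    # [B, C, S]
        parallel = self.parallel_bn(self.parallel_conv(x)).relu()
        return parallel * attended + x


class TransformerEncoderWithCLS(Module):
    """Post-norm Transformer encoder over ``[B, S, d]`` returning the CLS output.

    A learned CLS token is prepended at position 0 and learned positional
    embeddings (including one for the CLS slot) are added before the stack.
    """

    def __init__(self, d_model: int, n_steps: int, n_heads: int, ffn_dim: int,
                 n_layers: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.d_model = d_model
        scale = 1.0 / math.sqrt(d_model)
        self.cls_token = Parameter(rng.normal(0.0, scale, size=(1, 1, d_model)))
        self.pos_embedding = Parameter(rng.normal(0.0, scale, size=(1, n_steps + 1, d_model)))
        self.layers = [_EncoderLayer(d_model, n_heads, ffn_dim, dropout, rng)
                       for _ in range(n_layers)]

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        B, S, _ = x.shape
        if S == 0:
            raise ValueError("empty sequence")
        cls = self.cls_token * Tensor(np.ones((B, 1, 1)))
        h = cat([cls, x], axis=1) + self.pos_embedding
        for layer in self.layers:
            h = layer(h, rng)
        return h[:, 0, :]


class _EncoderLayer(Module):
    def __init__(self, d_model, n_heads, ffn_dim, dropout, rng):
        super().__init__()
        self.attn = MultiheadAttention(d_model, n_heads, rng)
        self.ffn1 = Linear(d_model, ffn_dim, rng)
        self.ffn2 = Linear(ffn_dim, d_model, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout)
        self.drop2 = Dropout(dropout)
        self.drop_ffn = Dropout(dropout)

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        h = self.norm1(x + self.drop1(self.attn(x, rng), rng))
        ffn = self.ffn2(self.drop_ffn(self.ffn1(h).relu(), rng))
        return self.norm2(h + self.drop2(ffn, rng))


class UncertaintyHead(Module):
    """Gaussian mean/variance heads on the CLS feature."""

    #: initial predictive variance (plausible residual scale for [0, 1] labels)
    INIT_VARIANCE = 0.1

    def __init__(self, d_model: int, rng: np.random.Generator, noise_mode: str = "var"):
        super().__init__()
        self.mu_head = Linear(d_model, 1, rng)
        self.logvar_head = Linear(d_model, 1, rng)
        # start near a constant prior variance so every modality enters
        # training with comparable confidence; the input dependence of the
        # variance is then learned rather than an artefact of random init
        self.logvar_head.weight.data *= 0.01
        self.logvar_head.bias.data[:] = math.log(self.INIT_VARIANCE)
        self.noise_mode = noise_mode

    def forward(self, cls_feature: Tensor,
                rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor, Tensor]:
        mu = self.mu_head(cls_feature).reshape(-1)
        sigma2 = self.logvar_head(cls_feature).reshape(-1).exp()
        if self.training:
            if rng is None:
                raise RuntimeError("training-mode sampling needs an rng")
            eps = Tensor(rng.standard_normal(mu.shape))
            noise = sigma2 if self.noise_mode == "var" else sigma2.sqrt()
            y_hat = mu + noise * eps
        else:
            y_hat = mu
        return mu, sigma2, y_hat


class UnimodalEncoder(Module):
    """Full per-modality pipeline: conv stack, Transformer, uncertainty head."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c = config
        self.conv1 = Conv1d(c.in_features, c.conv1_channels, c.kernel_size, rng,
                            padding_mode=c.padding_mode)
        self.csa1 = ConvSparseAttention(c.conv1_channels, c.attn_heads, rng,
                                        kernel_size=c.kernel_size,
                                        padding_mode=c.padding_mode)
        self.conv2 = Conv1d(c.conv1_channels, c.conv2_channels, c.kernel_size, rng,
                            padding_mode=c.padding_mode)
        self.csa2 = ConvSparseAttention(c.conv2_channels, c.attn_heads, rng,
                                        kernel_size=c.kernel_size,
                                        padding_mode=c.padding_mode)
        self.transformer = TransformerEncoderWithCLS(
            c.d_model, c.n_steps, c.attn_heads, c.ffn_dim, c.n_layers, c.dropout, rng)
        self.head = UncertaintyHead(c.d_model, rng, noise_mode=c.noise_mode)

    def conv_stack(self, x: Tensor, rng: np.random.Generator | None = None,
                   use_attention: bool | None = None) -> Tensor:
        """Convolutional front-end on ``[B, in_features, S]`` input."""
        if use_attention is None:
            use_attention = self.config.use_conv_sparse_attention
        h = self.conv1(x).relu()
        if use_attention:
            h = self.csa1(h, rng)
        h = self.conv2(h).relu()
        if use_attention:
            h = self.csa2(h, rng)
        return h

    def forward(self, x, rng: np.random.Generator | None = None) -> UnimodalOutput:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim != 3:
            raise ValueError(f"expected [B, n_steps, n_features], got {x.shape}")
        if x.shape[1] != self.config.n_steps or x.shape[2] != self.config.in_features:
            raise ValueError(
                f"input {x.shape[1:]} does not match configured "
                f"({self.config.n_steps}, {self.config.in_features})")
        h = self.conv_stack(x.swapaxes(1, 2), rng)        # [B, C2, S]
        cls = self.transformer(h.swapaxes(1, 2), rng)     # [B, d_model]
        mu, sigma2, y_hat = self.head(cls, rng)
        return UnimodalOutput(mu=mu, sigma2=sigma2, y_hat=y_hat, cls_feature=cls)
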