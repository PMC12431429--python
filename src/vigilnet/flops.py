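"""Analytic operation counting for one forward pass.

Convention: every multiply-accumulate (MAC) inside a matrix product counts
as 2 FLOPs (one multiply, one add).  Counted operations are the linear
layers, convolutions and attention products (QKV/output projections, score
and attention-value products) of every module; elementwise activations,
normalisations and softmaxes are not counted, following the usual
profiler convention.  Counts are per sample (batch size 1).
"""

from __future__ import annotations

from .encoder import EncoderConfig
from .fusion import FusionConfig
from .model import MODALITY_ORDER, MultimodalVigilanceNet

__all__ = ["linear_macs", "conv1d_macs", "attention_macs", "encoder_macs",
           "fusion_macs", "count_macs", "count_flops"]


def linear_macs(in_features: int, out_features: int, positions: int = 1) -> int:
    """MACs of an affine map applied at ``positions`` sequence positions."""
    return in_features * out_features * positions


def conv1d_macs(in_channels: int, out_channels: int, kernel_size: int, seq_len: int,
                groups: int = 1) -> int:
    return seq_len * out_channels * (in_channels // groups) * kernel_size


def attention_macs(seq_len: int, d_model: int) -> int:
    """Multi-head self-attention: QKV + output projections, scores, values."""
    projections = 4 * linear_macs(d_model, d_model, seq_len)
    scores_and_values = 2 * seq_len * seq_len * d_model
    return projections + scores_and_values


def _csa_macs(channels: int, seq_len: int, kernel_size: int) -> int:
    compress = conv1d_macs(channels, 1, 1, seq_len)
    depthwise = conv1d_macs(channels, channels, kernel_size, seq_len, groups=channels)
    pointwise = conv1d_macs(channels, channels, 1, seq_len)
    attention = attention_macs(seq_len, channels)
    parallel = conv1d_macs(channels, channels, kernel_size, seq_len)
    return compress + depthwise + pointwise + attention + parallel


def encoder_macs(config: EncoderConfig) -> int:
    c, S = config, config.n_steps
    total = conv1d_macs(c.in_features, c.conv1_channels, c.kernel_size, S)
    total += conv1d_macs(c.conv1_channels, c.conv2_channels, c.kernel_size, S)
    if c.use_conv_sparse_attention:
        total += _csa_macs(c.conv1_channels, S, c.kernel_size)
        total += _csa_macs(c.conv2_channels, S, c.kernel_size)
    tokens = S + 1  # CLS prepended
    per_layer = attention_macs(tokens, c.d_model) + 2 * linear_macs(c.d_model, c.ffn_dim, tokens)
    total += c.n_layers * per_layer
    total += 2 * linear_macs(c.d_model, 1)  # mean and log-variance heads
    return total


def fusion_macs(config: FusionConfig, cls_dims: list[int]) -> int:
    d, T = config.d_model, 3
    total = sum(linear_macs(dim, d) for dim in cls_dims)      # modality projections
    total += attention_macs(T, d)
    total += linear_macs(3, config.n_heads * 3)               # confidence projection
    total += linear_macs(6, config.hidden1) + linear_macs(config.hidden1, config.hidden2)
    total += linear_macs(2 * d, d) + linear_macs(d, d)        # gate
    total += linear_macs(d, config.hidden1) + linear_macs(config.hidden1, 1)  # fused branch
    total += linear_macs(6, config.hidden1) + linear_macs(config.hidden1, 1)  # residual branch
    return total


def count_macs(model: MultimodalVigilanceNet) -> dict[str, int]:
    """Per-component MAC counts of one forward pass at batch size 1."""
    counts = {name: encoder_macs(model.encoders[name].config) for name in MODALITY_ORDER}
    cls_dims = [model.encoders[name].config.d_model for name in MODALITY_ORDER]
    counts["fusion"] = fusion_macs(model.fusion_config, cls_dims)
    counts["total"] = sum(counts.values())
    return counts


def count_flops(model: MultimodalVigilanceNet) -> float:
    """Forward-pass cost in GFLOPs (2 FLOPs per MAC)."""
    return 2.0 * count_macs(model)["total"] / 1e9
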