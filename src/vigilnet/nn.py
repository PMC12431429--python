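"""Neural-network building blocks on top of the autodiff engine.

Layers follow the conventional module pattern: parameters are
:class:`~vigilnet._tensor.Parameter` attributes, ``train()``/``eval()``
toggle stochastic behaviour (dropout, batch statistics), and modules are
callable.  Stochastic layers draw from a generator passed explicitly at
call time so the whole network is reproducible from a single seed.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from ._tensor import (Parameter, Tensor, affine, cat, conv1d_fused,
                      layernorm_fused, softmax_fused)

__all__ = [
    "Module",
    "Linear",
    "CausalConv1d",
    "Conv1d",
    "LayerNorm",
    "BatchNorm1d",
    "Dropout",
    "MultiheadAttention",
    "softmax",
]


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return softmax_fused(x, axis=axis)


class Module:
    """Base class: parameter discovery, train/eval mode, call protocol."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def children(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item
            elif isinstance(value, dict):
                for item in value.values():
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self.children():
            yield from child.modules()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for module in self.modules():
            for value in module.__dict__.values():
                if isinstance(value, Parameter):
                    params.append(value)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((path, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=path + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{path}.{i}."))
            elif isinstance(value, dict):
                for key, item in value.items():
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{path}.{key}."))
        return out

    def train(self, mode: bool = True) -> "Module":
        for module in self.modules():
            module.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    """Affine map ``x @ W + b`` with Kaiming-uniform initialisation."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(out_features,))) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return affine(x, self.weight, self.bias)


class Conv1d(Module):
    """1-D convolution over ``[B, C_in, S]``, stride 1.

    ``padding_mode`` selects how the sequence is padded:

    * ``"causal"`` — left-only zero padding of ``kernel_size - 1``, so the
      output at step *t* depends only on inputs at steps ``<= t``;
    * ``"replicate"`` — symmetric edge replication of width
      ``(kernel_size - 1) // 2`` (requires an odd kernel).

    Grouped (depthwise) convolution is supported through ``groups``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding_mode: str = "causal",
                 groups: int = 1, bias: bool = True):
        super().__init__()
        if padding_mode not in ("causal", "replicate"):
            raise ValueError(f"unknown padding_mode {padding_mode!r}")
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        if padding_mode == "replicate" and kernel_size % 2 == 0:
            raise ValueError("replicate padding requires an odd kernel")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding_mode = padding_mode
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size
        bound = 1.0 / math.sqrt(fan_in)
        # weight[j] is the tap applied to the slice offset j, shape [groups, C_in/g, C_out/g]
        self.weight = Parameter(
            rng.uniform(-bound, bound,
                        size=(kernel_size, groups, in_channels // groups, out_channels // groups)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(out_channels,))) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] < 1:
            raise ValueError("empty sequence")
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {x.shape[1]}")
        return conv1d_fused(x, self.weight, self.bias, self.kernel_size,
                            self.groups, self.padding_mode)


class CausalConv1d(Conv1d):
    """Convenience alias for :class:`Conv1d` with causal padding."""

    def __init__(self, in_channels, out_channels, kernel_size, rng, **kwargs):
        kwargs.setdefault("padding_mode", "causal")
        super().__init__(in_channels, out_channels, kernel_size, rng, **kwargs)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        return layernorm_fused(x, self.weight, self.bias, self.eps)


class BatchNorm1d(Module):
    """Per-channel batch norm over ``[B, C, S]`` with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            normed = centred / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, -1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1)
            normed = (x - Tensor(mu)) / Tensor(sd)
        return normed * self.weight.reshape(1, self.channels, 1) \
            + self.bias.reshape(1, self.channels, 1)


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if rng is None:
            raise RuntimeError("dropout in training mode needs an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiheadAttention(Module):
    """Standard multi-head self-attention over ``[B, T, D]``."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.head_dim = d_model // n_heads
        self.q_proj = Linear(d_model, d_model, rng)
        self.k_proj = Linear(d_model, d_model, rng)
        self.v_proj = Linear(d_model, d_model, rng)
        self.out_proj = Linear(d_model, d_model, rng)
        self.attn_dropout = Dropout(dropout)

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor, rng: np.random.Generator | None = None,
                return_weights: bool = False):
        B, T, _ = x.shape
        q = self._split(self.q_proj(x), B, T)
        k = self._split(self.k_proj(x), B, T)
        v = self._split(self.v_proj(x), B, T)
        scores = (q @ k.transpose(0, 1, 3, 2)) / math.sqrt(self.head_dim)
        attn = softmax(scores, axis=-1)
        attn = self.attn_dropout(attn, rng)
        out = attn @ v                                       # [B, H, T, d_h]
        out = out.transpose(0, 2, 1, 3).reshape(B, T, self.d_model)
        out = self.out_proj(out)
        if return_weights:
            return out, attn
        return out
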