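"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine in the spirit of the classic define-by-run
frameworks: a :class:`Tensor` wraps an ``ndarray``, records the operation
that produced it, and :meth:`Tensor.backward` walks the tape in reverse
topological order accumulating gradients.  Only the operations the vigilance
network needs are implemented (elementwise arithmetic, batched ``matmul``,
reductions, shape manipulation, slicing and the usual activations); all
arrays are ``float64``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "cat", "stack", "affine", "conv1d_fused",
           "softmax_fused", "layernorm_fused"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(value) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64)
    return arr


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(value) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    @staticmethod
    def _node(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return self._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._node(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):  # pragma: no cover - unused path
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return self._node(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            da = db = None
            if self.requires_grad:
                da = _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape)
            if other.requires_grad:
                db = _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape)
            return da, db

        return self._node(out_data, (self, other), backward)

    # -- elementwise functions ------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return self._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return self._node(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            return (g / (2.0 * out_data),)

        return self._node(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return self._node(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return self._node(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out_data**2),)

        return self._node(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / count

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape

        def backward(g):
            return (g.reshape(old_shape),)

        return self._node(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = tuple(np.argsort(axes))

        def backward(g):
            return (g.transpose(inverse),)

        return self._node(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            return (np.swapaxes(g, a, b),)

        return self._node(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, index):
        out_data = self.data[index]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, index, g)
            return (full,)

        return self._node(out_data, (self,), backward)

    # -- autograd driver ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("called backward() on a tensor without grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for parent, pg in zip(node._parents, parent_grads):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # leaves that are also the output node
        if self._backward is None and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)


class Parameter(Tensor):
    """A trainable tensor (always tracks gradients)."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def affine(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Fused ``x @ weight + bias`` (one tape node instead of two)."""
    x = Tensor._lift(x)
    out_data = x.data @ weight.data
    if bias is not None:
        out_data = out_data + bias.data

    def backward(g):
        dx = dw = db = None
        if x.requires_grad:
            dx = g @ weight.data.T
        if weight.requires_grad:
            xf = x.data.reshape(-1, x.data.shape[-1])
            gf = g.reshape(-1, g.shape[-1])
            dw = xf.T @ gf
        if bias is not None and bias.requires_grad:
            db = g.reshape(-1, g.shape[-1]).sum(axis=0)
        return (dx, dw, db) if bias is not None else (dx, dw)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._node(out_data, parents, backward)


def conv1d_fused(x: Tensor, weight: Tensor, bias: Tensor | None, kernel_size: int,
                 groups: int, padding_mode: str) -> Tensor:
    """Grouped 1-D convolution as a single tape node.

    ``x`` is ``[B, C_in, S]``; ``weight`` is ``[k, groups, C_in/g, C_out/g]``.
    ``padding_mode`` is ``"causal"`` (left zero pad of k-1) or ``"replicate"``
    (symmetric edge pad of (k-1)/2).
    """
    from numpy.lib.stride_tricks import sliding_window_view

    B, C_in, S = x.data.shape
    k, g = kernel_size, groups
    c_out_per = weight.data.shape[3]
    if padding_mode == "causal":
        left, right = k - 1, 0
    else:
        left = right = (k - 1) // 2
    if padding_mode == "causal":
        padded = np.concatenate([np.zeros((B, C_in, left)), x.data], axis=2)
    else:
        padded = np.pad(x.data, ((0, 0), (0, 0), (left, right)), mode="edge")
    windows = sliding_window_view(padded, k, axis=2)         # [B, C_in, S, k]
    win = windows.reshape(B, g, C_in // g, S, k)
    out = np.einsum("bgisk,kgio->bgos", win, weight.data, optimize=True)
    out_data = out.reshape(B, g * c_out_per, S)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, -1, 1)

    def backward(grad):
        dx = dw = db = None
        go = grad.reshape(B, g, c_out_per, S)
        if weight.requires_grad:
            dw = np.einsum("bgisk,bgos->kgio", win, go, optimize=True)
        if x.requires_grad:
            dwin = np.einsum("bgos,kgio->bgisk", go, weight.data, optimize=True)
            dpadded = np.zeros_like(padded)
            for j in range(k):
                dpadded[:, :, j:j + S] += dwin[..., j].reshape(B, C_in, S)
            dx = dpadded[:, :, left:left + S].copy()
            if padding_mode == "replicate" and left > 0:
                dx[:, :, 0] += dpadded[:, :, :left].sum(axis=2)
                dx[:, :, -1] += dpadded[:, :, left + S:].sum(axis=2)
        if bias is not None and bias.requires_grad:
            db = grad.sum(axis=(0, 2))
        return (dx, dw, db) if bias is not None else (dx, dw)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._node(out_data, parents, backward)


def softmax_fused(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax as a single tape node."""
    x = Tensor._lift(x)
    shifted = x.data - np.max(x.data, axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return (out_data * (g - dot),)

    return Tensor._node(out_data, (x,), backward)


def layernorm_fused(x: Tensor, weight: Tensor, bias: Tensor, eps: float) -> Tensor:
    """Layer normalisation over the last axis as a single tape node."""
    x = Tensor._lift(x)
    mu = x.data.mean(axis=-1, keepdims=True)
    centred = x.data - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    inv_sd = 1.0 / np.sqrt(var + eps)
    xhat = centred * inv_sd
    out_data = xhat * weight.data + bias.data

    def backward(g):
        dx = dw = db = None
        if x.requires_grad:
            dxhat = g * weight.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            dx = (dxhat - m1 - xhat * m2) * inv_sd
        if weight.requires_grad:
            dw = (g * xhat).reshape(-1, g.shape[-1]).sum(axis=0)
        if bias.requires_grad:
            db = g.reshape(-1, g.shape[-1]).sum(axis=0)
        return dx, dw, db

    return Tensor._node(out_data, (x, weight, bias), backward)


def cat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(out_data, tensors, backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        pieces = np.split(g, len(tensors), axis=axis)
        return tuple(np.squeeze(p, axis=axis) for p in pieces)

    return Tensor._node(out_data, tensors, backward)
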