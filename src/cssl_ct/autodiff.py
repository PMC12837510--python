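"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tensor engine sufficient for training compact vision transformers on
a CPU: broadcasting arithmetic, batched matrix products, reductions, gather,
and fused transformer nonlinearities (tanh-GELU, softmax, layer norm).
Gradients are accumulated lazily by reverse topological traversal of the
recorded graph; each forward pass records a fresh graph.

Dtype follows the inputs: float32 model weights give float32 graphs (the
training path), while float64 inputs stay float64 (the oracle/test path).
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "concat",
    "broadcast_to",
    "no_grad",
    "softmax",
    "log_softmax",
    "layer_norm",
]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _accum(t: "Tensor", g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = _unbroadcast(g, t.data.shape)
    t.grad = g if t.grad is None else t.grad + g


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _make(self, data, parents) -> "Tensor":
        req = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):
            out = self._make(self.data + other, (self,))
            out._backward = lambda: _accum(self, out.grad)
            return out
        other = astensor(other)
        out = self._make(self.data + other.data, (self, other))

        def backward():
            _accum(self, out.grad)
            _accum(other, out.grad)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,))
        out._backward = lambda: _accum(self, -out.grad)
        return out

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        other = astensor(other)
        out = self._make(self.data - other.data, (self, other))

        def backward():
            _accum(self, out.grad)
            _accum(other, -out.grad)

        out._backward = backward
        return out

    def __rsub__(self, other):
        return astensor(other) - self

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = self._make(self.data * other, (self,))
            out._backward = lambda: _accum(self, out.grad * other)
            return out
        other = astensor(other)
        out = self._make(self.data * other.data, (self, other))

        def backward():
            _accum(self, out.grad * other.data)
            _accum(other, out.grad * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = astensor(other)
        out = self._make(self.data / other.data, (self, other))

        def backward():
            _accum(self, out.grad / other.data)
            _accum(other, -out.grad * self.data / (other.data * other.data))

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = self._make(self.data**exponent, (self,))

        def backward():
            _accum(self, out.grad * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = self._make(self.data @ other.data, (self, other))

        def backward():
            g = out.grad
            if self.requires_grad:
                _accum(self, g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                _accum(other, np.swapaxes(self.data, -1, -2) @ g)

        out._backward = backward
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out = self._make(np.exp(self.data), (self,))
        out._backward = lambda: _accum(self, out.grad * out.data)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,))
        out._backward = lambda: _accum(self, out.grad / self.data)
        return out

    def sqrt(self):
        out = self._make(np.sqrt(self.data), (self,))
        out._backward = lambda: _accum(self, out.grad * 0.5 / out.data)
        return out

    def tanh(self):
        out = self._make(np.tanh(self.data), (self,))
        out._backward = lambda: _accum(self, out.grad * (1.0 - out.data * out.data))
        return out

    def gelu(self):
        """Gaussian error linear unit (tanh approximation), fused."""
        x = self.data
        c = math.sqrt(2.0 / math.pi)
        t = np.tanh(c * (x + 0.044715 * (x * x * x)))
        out = self._make(0.5 * x * (1.0 + t), (self,))

        def backward():
            dinner = c * (1.0 + 3 * 0.044715 * (x * x))
            _accum(self, out.grad * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner))

        out._backward = backward
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            _accum(self, np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,))
        out._backward = lambda: _accum(self, out.grad.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = self._make(self.data.transpose(axes), (self,))
        inv = tuple(np.argsort(axes))
        out._backward = lambda: _accum(self, out.grad.transpose(inv))
        return out

    def take(self, indices, axis: int):
        """Select along ``axis`` with a 1-D integer index array (gather)."""
        indices = np.asarray(indices)
        if indices.ndim != 1:
            raise ValueError("take() supports 1-D index arrays only")
        out = self._make(np.take(self.data, indices, axis=axis), (self,))

        def backward():
            g_full = np.zeros_like(self.data)
            np.add.at(np.moveaxis(g_full, axis, 0), indices, np.moveaxis(out.grad, axis, 0))
            _accum(self, g_full)

        out._backward = backward
        return out

    # -- autodiff driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            if node is not self:
                node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = _grad_enabled and any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        ax = axis % data.ndim

        def backward():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                sl = tuple(slice(lo, hi) if a == ax else slice(None) for a in range(data.ndim))
                _accum(t, out.grad[sl])

        out._backward = backward
    return out


def broadcast_to(t: Tensor, shape: tuple) -> Tensor:
    t = astensor(t)
    out = t._make(np.broadcast_to(t.data, shape), (t,))
    out._backward = lambda: _accum(t, out.grad)  # _accum unbroadcasts
    return out


# -- fused composite ops used by the transformer -------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = astensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = x._make(s, (x,))

    def backward():
        g = out.grad
        _accum(x, s * (g - (g * s).sum(axis=axis, keepdims=True)))

    out._backward = backward
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = astensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    out = x._make(out_data, (x,))

    def backward():
        g = out.grad
        _accum(x, g - np.exp(out_data) * g.sum(axis=axis, keepdims=True))

    out._backward = backward
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Fused layer normalization over the last axis."""
    x, gain, bias = astensor(x), astensor(gain), astensor(bias)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = x._make(xhat * gain.data + bias.data, (x, gain, bias))

    def backward():
        g = out.grad
        _accum(gain, g * xhat)
        _accum(bias, g)
        if x.requires_grad:
            gg = g * gain.data
            n = x.data.shape[-1]
            dx = inv * (
                gg
                - gg.mean(axis=-1, keepdims=True)
                - xhat * (gg * xhat).mean(axis=-1, keepdims=True)
            )
            _accum(x, dx)

    out._backward = backward
    return out
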