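"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
``Tensor.backward()`` walks the tape in reverse topological order and
accumulates gradients into every tensor built with ``requires_grad=True``.
Only the operations the classifier architectures need are implemented:
broadcast arithmetic, (batched) matmul, the usual pointwise nonlinearities,
reductions, shape ops, softmax, 1-D convolution/max-pooling with fused
backward passes, and a fused softmax cross-entropy loss.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

__all__ = ["Tensor", "conv1d", "maxpool1d", "cross_entropy_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        if isinstance(data, (np.ndarray, np.generic)):
            self.data = np.asarray(data)
        else:
            self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # -- infrastructure -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None):
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, self._needs(other), (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, self._needs(other), (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self.pow(-1.0)

    def pow(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))
        out._backward = bwd
        return out

    def matmul(self, other: "Tensor"):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, self._needs(other), (self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- nonlinearities -----------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))
        out._backward = bwd
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y ** 2))
        out._backward = bwd
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))
        out._backward = bwd
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    def sqrt(self):
        return self.pow(0.5)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot))
        out._backward = bwd
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            scale = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            scale = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / scale)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))
        out._backward = bwd
        return out

    def slice_last(self, start: int, stop: int):
        """Static slice along the last axis (used to split fused projections)."""
        out = Tensor(self.data[..., start:stop], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[..., start:stop] = g
                self._accum(full)
        out._backward = bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


# -- fused structured ops ---------------------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """'Same'-padded 1-D correlation.

    ``x``: (B, C, L); ``w``: (O, C, K) with K odd; ``b``: (O,).
    Output (B, O, L).  Implemented as an im2col matmul with an explicit
    backward pass (the input gradient is the transposed-kernel convolution).
    """
    B, C, L = x.data.shape
    O, C2, K = w.data.shape
    assert C == C2 and K % 2 == 1, "conv1d needs matching channels and odd K"
    p = (K - 1) // 2

    def _cols(arr, pad):
        ap = np.pad(arr, ((0, 0), (0, 0), (pad, pad)))
        win = np.lib.stride_tricks.sliding_window_view(ap, K, axis=2)  # (B,C,L,K)
        return win.transpose(0, 2, 1, 3).reshape(arr.shape[0] * arr.shape[2], -1)

    colmat = _cols(x.data, p)                                  # (B*L, C*K)
    out_mat = colmat @ w.data.reshape(O, -1).T                 # (B*L, O)
    out_data = out_mat.reshape(B, L, O).transpose(0, 2, 1)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_data, any(t.requires_grad for t in prev), prev)

    def bwd(g):
        gmat = g.transpose(0, 2, 1).reshape(B * L, O)
        if w.requires_grad:
            w._accum((gmat.T @ colmat).reshape(O, C, K))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            w_flip = w.data[:, :, ::-1].transpose(1, 0, 2)     # (C, O, K)
            gcols = _cols(g, p)                                # (B*L, O*K)
            gx = (gcols @ w_flip.reshape(C, -1).T).reshape(B, L, C).transpose(0, 2, 1)
            x._accum(gx)
    out._backward = bwd
    return out


def maxpool1d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping max pooling over the last axis; requires k | L."""
    B, C, L = x.data.shape
    assert L % k == 0, "pooling needs the length divisible by the pool size"
    xr = x.data.reshape(B, C, L // k, k)
    idx = xr.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0],
                 x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            gr = np.zeros_like(xr)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            x._accum(gr.reshape(B, C, L))
    out._backward = bwd
    return out


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch of logits (B, K)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    B = len(labels)
    loss = -logp[np.arange(B), labels].mean()
    out = Tensor(np.asarray(loss, dtype=logits.data.dtype),
                 logits.requires_grad, (logits,))

    def bwd(g):
        if logits.requires_grad:
            probs = np.exp(logp)
            probs[np.arange(B), labels] -= 1.0
            logits._accum(g * probs / B)
    out._backward = bwd
    return out


def parameters_of(tensors: Iterable[Tensor]):
    return [t for t in tensors if t.requires_grad]
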