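"""Neural-network building blocks on top of the autograd tape.

Every layer is a :class:`Module` holding its parameters as ``Tensor``s with
``requires_grad=True``.  Initialization draws from a caller-supplied numpy
``Generator``, so two builds from the same seed are bitwise identical.
Parameters are float32.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .autograd import Tensor, conv1d, maxpool1d

__all__ = [
    "Module", "Sequential", "Linear", "Conv1d", "BatchNorm1d", "ReLU",
    "MaxPool1d", "GlobalAvgPool", "Dropout", "LSTM", "LayerNorm",
    "MultiHeadSelfAttention", "FeedForward", "TransformerEncoderLayer",
    "LearnablePositionalEncoding",
]


def _f32(a) -> np.ndarray:
    return np.asarray(a, dtype=np.float32)


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def submodules(self) -> List["Module"]:
        subs: List[Module] = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                subs.append(v)
                subs.extend(v.submodules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        subs.append(item)
                        subs.extend(item.submodules())
        return subs

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.submodules():
            m.training = mode
        return self

    _buffers: tuple = ()

    def named_buffers(self):
        """(module, attribute) pairs for non-trainable state (e.g. batch-norm
        running statistics), over this module and all submodules."""
        out = [(self, name) for name in self._buffers]
        for m in self.submodules():
            out.extend((m, name) for name in m._buffers)
        return out

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
        self.w = Tensor(_f32(rng.uniform(-bound, bound, (d_in, d_out))), True)
        self.b = Tensor(np.zeros(d_out, dtype=np.float32), True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """'Same' 1-D convolution over (B, C, L) maps."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * kernel_size
        bound = np.sqrt(6.0 / fan_in)  # He-style uniform for ReLU stacks
        self.kernel_size = kernel_size
        self.w = Tensor(_f32(rng.uniform(-bound, bound, (c_out, c_in, kernel_size))), True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), True)

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b)


class BatchNorm1d(Module):
    """Per-channel batch normalization over (B, C, L) maps."""

    _buffers = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones((1, channels, 1), dtype=np.float32), True)
        self.beta = Tensor(np.zeros((1, channels, 1), dtype=np.float32), True)
        self.running_mean = np.zeros((1, channels, 1), dtype=np.float32)
        self.running_var = np.ones((1, channels, 1), dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu.detach()) * (x - mu.detach())).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            xhat = (x - mu) * (var + self.eps).pow(-0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool1d(Module):
    def __init__(self, pool_size: int):
        super().__init__()
        self.pool_size = pool_size

    def forward(self, x: Tensor) -> Tensor:
        return maxpool1d(x, self.pool_size)


class GlobalAvgPool(Module):
    """Mean over the last axis of (B, C, L) — or the middle axis of (B, T, D)
    when ``axis`` says so."""

    def __init__(self, axis: int = -1):
        super().__init__()
        self.axis = axis

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=self.axis)


class Dropout(Module):
    def __init__(self, p: float, rng: Optional[np.random.Generator] = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class LSTM(Module):
    """Single-layer LSTM over (B, T, D) sequences, returning (B, T, H).

    Standard gate structure: forget, input, candidate, output, with fused
    input/recurrent projections.  Parameter count is
    4*(H*(D+H) + H) for the recurrent core.
    """

    def __init__(self, d_in: int, n_units: int, rng: np.random.Generator):
        super().__init__()
        if n_units < 1:
            raise ValueError("n_units must be >= 1")
        self.n_units = n_units
        bound = np.sqrt(6.0 / (d_in + n_units))
        self.wx = Tensor(_f32(rng.uniform(-bound, bound, (d_in, 4 * n_units))), True)
        bound_h = np.sqrt(6.0 / (2 * n_units))
        self.wh = Tensor(_f32(rng.uniform(-bound_h, bound_h, (n_units, 4 * n_units))), True)
        bias = np.zeros(4 * n_units, dtype=np.float32)
        bias[:n_units] = 1.0  # forget-gate bias starts open
        self.b = Tensor(bias, True)

    def forward(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.n_units
        h = Tensor(np.zeros((B, H), dtype=np.float32))
        c = Tensor(np.zeros((B, H), dtype=np.float32))
        outs = []
        for t in range(T):
            xt = _TimeStep(x, t)
            gates = xt @ self.wx + h @ self.wh + self.b
            f = gates.slice_last(0, H).sigmoid()
            i = gates.slice_last(H, 2 * H).sigmoid()
            g = gates.slice_last(2 * H, 3 * H).tanh()
            o = gates.slice_last(3 * H, 4 * H).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return _stack_time(outs)

    def last_hidden(self, x: Tensor) -> Tensor:
        seq = self.forward(x)
        return _TimeStep(seq, seq.shape[1] - 1)


def _TimeStep(x: Tensor, t: int) -> Tensor:
    """Select timestep t of a (B, T, D) tensor -> (B, D), differentiable."""
    out = Tensor(x.data[:, t, :], x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, t, :] = g
            x._accum(full)
    out._backward = bwd
    return out


def _stack_time(steps: List[Tensor]) -> Tensor:
    """Stack a list of (B, D) tensors into (B, T, D), differentiable."""
    data = np.stack([s.data for s in steps], axis=1)
    out = Tensor(data, any(s.requires_grad for s in steps), tuple(steps))

    def bwd(g):
        for t, s in enumerate(steps):
            if s.requires_grad:
                s._accum(g[:, t, :])
    out._backward = bwd
    return out


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d, dtype=np.float32), True)
        self.beta = Tensor(np.zeros(d, dtype=np.float32), True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """MHSA over (B, T, D): fused QKV projection, per-head scaled dot-product
    attention, output projection."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.qkv = Linear(d_model, 3 * d_model, rng)
        self.out = Linear(d_model, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        H, dh = self.n_heads, self.d_head
        qkv = self.qkv(x)                                       # (B,T,3D)
        q = qkv.slice_last(0, D).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        k = qkv.slice_last(D, 2 * D).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        v = qkv.slice_last(2 * D, 3 * D).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        mixed = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.out(mixed)


class FeedForward(Module):
    """Position-wise feedforward network (two linear layers, ReLU)."""

    def __init__(self, d_model: int, ffn_dim: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d_model, ffn_dim, rng)
        self.fc2 = Linear(ffn_dim, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: MHSA and FFN, each followed by a residual
    connection and layer normalization."""

    def __init__(self, d_model: int, n_heads: int, ffn_dim: int,
                 dropout_rate: float, rng: np.random.Generator):
        super().__init__()
        self.mhsa = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, ffn_dim, rng)
        self.norm2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout_rate, np.random.default_rng(rng.integers(2 ** 31)))
        self.drop2 = Dropout(dropout_rate, np.random.default_rng(rng.integers(2 ** 31)))

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop1(self.mhsa(x)))
        x = self.norm2(x + self.drop2(self.ffn(x)))
        return x


class LearnablePositionalEncoding(Module):
    """Additive learnable positional encoding for (B, T, D) sequences."""

    def __init__(self, n_tokens: int, d_model: int, rng: np.random.Generator):
        super().__init__()
        self.pe = Tensor(_f32(0.02 * rng.standard_normal((1, n_tokens, d_model))), True)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.pe
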