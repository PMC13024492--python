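"""The three mass-load classifier architectures.

Each builder returns a :class:`Classifier` whose forward pass maps a batch
of featurized segments to a 10-class probability distribution:

* CNN — repeated feature-extraction blocks (convolution, batch norm, ReLU,
  max pooling) over the dual-channel raw+FFT input, then average pooling,
  dropout, one fully connected layer and softmax.
* LSTM — a recurrent layer with ``n_units`` memory blocks over a timestep
  sequence, 20% dropout, one fully connected layer and softmax.
* Transformer — patches linearly projected to ``d_model`` (X_emb), plus a
  learnable positional encoding (X_pos), through L encoder layers of
  multi-head self-attention and a feedforward network with residuals and
  layer normalization (H_final), global average pooling over the token
  dimension (H_pooled), one fully connected layer and softmax.

The sweep axes are ``n_blocks`` (CNN), ``n_units`` (LSTM) and ``L``
(Transformer); everything else is a recorded default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List, Optional

import numpy as np

from .errors import ConfigurationError
from . import nn
from .nn.autograd import Tensor

__all__ = [
    "CNNConfig", "LSTMConfig", "TransformerConfig", "Classifier",
    "build_cnn", "build_lstm", "build_transformer", "build_model",
]

N_CLASSES = 10


@dataclass(frozen=True)
class CNNConfig:
    n_blocks: int = 7
    kernel_size: int = 9
    base_channels: int = 16
    channel_cap: int = 128
    channels_per_block: Optional[tuple] = None  # overrides the doubling rule
    pool_size: int = 2
    dropout_rate: float = 0.3
    n_classes: int = N_CLASSES

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.kernel_size % 2 == 0:
            raise ConfigurationError("kernel_size must be odd ('same' padding)")
        if self.channels_per_block is not None and \
                len(self.channels_per_block) != self.n_blocks:
            raise ConfigurationError("channels_per_block must match n_blocks")

    def channels(self) -> List[int]:
        if self.channels_per_block is not None:
            return list(self.channels_per_block)
        return [min(self.base_channels * 2 ** i, self.channel_cap)
                for i in range(self.n_blocks)]


@dataclass(frozen=True)
class LSTMConfig:
    n_units: int = 140
    dropout_rate: float = 0.2
    n_classes: int = N_CLASSES

    def __post_init__(self):
        if self.n_units < 1:
            raise ConfigurationError("n_units must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TransformerConfig:
    L: int = 18
    d_model: int = 64
    n_heads: int = 4
    ffn_dim: int = 128
    T: int = 48
    C: int = 1
    dropout_rate: float = 0.1
    n_classes: int = N_CLASSES

    def __post_init__(self):
        if self.L < 1:
            raise ConfigurationError("L must be >= 1")
        if self.d_model % self.n_heads != 0:
            raise ConfigurationError("d_model must be divisible by n_heads")


def _pad_last(x: Tensor, total: int) -> Tensor:
    """Zero-pad the last axis of (B, C, L) up to ``total``, differentiable."""
    B, C, L = x.data.shape
    if L == total:
        return x
    out_data = np.zeros((B, C, total), dtype=x.data.dtype)
    out_data[:, :, :L] = x.data
    out = Tensor(out_data, x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g[:, :, :L])
    out._backward = bwd
    return out


class _PadToMultiple(nn.Module):
    def __init__(self, multiple: int):
        super().__init__()
        self.multiple = multiple

    def forward(self, x: Tensor) -> Tensor:
        L = x.data.shape[-1]
        target = -(-L // self.multiple) * self.multiple
        return _pad_last(x, target)


class _ToChannelsFirst(nn.Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.transpose(0, 2, 1)


class Classifier:
    """A built model: forward contract (probabilities over 10 classes),
    structural introspection, and checkpoint (de)serialization."""

    def __init__(self, arch: str, config, net: nn.Sequential, seed: int,
                 input_hint: str):
        self.arch = arch
        self.config = config
        self.net = net
        self.seed = seed
        self.input_hint = input_hint

    # -- forward ------------------------------------------------------------

    def forward_logits(self, x: np.ndarray) -> Tensor:
        return self.net(Tensor(np.asarray(x, dtype=np.float32)))

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities, computed in inference mode."""
        was_training = self.net.training
        self.net.eval()
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward_logits(x[i:i + batch_size]).softmax(-1).data)
        self.net.train(was_training)
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Argmax class indices (ties break to the lowest index)."""
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- structure ----------------------------------------------------------

    def modules(self) -> list:
        return self.net.submodules()

    def count_layers(self, layer_type) -> int:
        return sum(isinstance(m, layer_type) for m in self.modules())

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def parameters(self):
        return self.net.parameters()

    def train(self, mode: bool = True):
        self.net.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- checkpointing ------------------------------------------------------

    def get_state(self) -> list:
        """Copies of all trainable parameters and persistent buffers
        (batch-norm running statistics), in a stable order."""
        arrays = [p.data.copy() for p in self.parameters()]
        arrays += [getattr(m, name).copy() for m, name in self.net.named_buffers()]
        return arrays

    def set_state(self, arrays: list):
        params = self.parameters()
        for p, a in zip(params, arrays):
            p.data[...] = a
        for (m, name), a in zip(self.net.named_buffers(), arrays[len(params):]):
            getattr(m, name)[...] = a
        return self

    def metadata(self) -> dict:
        return {"arch": self.arch, "seed": self.seed,
                "input_hint": self.input_hint, "config": asdict(self.config)}

    def save(self, path: str):
        """Write ``<path>.npz`` (parameters + buffers) and ``<path>.json``
        (metadata)."""
        arrays = {f"s{i}": a for i, a in enumerate(self.get_state())}
        np.savez(str(path) + ".npz", **arrays)
        with open(str(path) + ".json", "w") as fh:
            json.dump(self.metadata(), fh, indent=2, sort_keys=True)

    def load(self, path: str):
        with np.load(str(path) + ".npz") as data:
            self.set_state([data[f"s{i}"] for i in range(len(data.files))])
        return self


def build_cnn(cfg: CNNConfig, input_length: int = 4800, in_channels: int = 2,
              seed: int = 0) -> Classifier:
    """Convolutional classifier over (B, N, C) dual-channel inputs."""
    rng = np.random.default_rng(seed)
    layers: list = [_ToChannelsFirst()]
    c_in = in_channels
    length = input_length
    for i, c_out in enumerate(cfg.channels()):
        if length < 1:
            raise ConfigurationError(
                f"feature block {i + 1} receives an empty map: pooling has "
                f"collapsed the input length to zero")
        layers += [nn.Conv1d(c_in, c_out, cfg.kernel_size, rng),
                   nn.BatchNorm1d(c_out), nn.ReLU(),
                   _PadToMultiple(cfg.pool_size), nn.MaxPool1d(cfg.pool_size)]
        length //= cfg.pool_size  # tracked without padding for the collapse check
        c_in = c_out
    layers += [nn.GlobalAvgPool(axis=-1),
               nn.Dropout(cfg.dropout_rate, np.random.default_rng(rng.integers(2 ** 31))),
               nn.Linear(c_in, cfg.n_classes, rng)]
    return Classifier("cnn", cfg, nn.Sequential(*layers), seed, "dual_channel")


class _LSTMHead(nn.Module):
    def __init__(self, cfg: LSTMConfig, d_in: int, rng: np.random.Generator):
        super().__init__()
        self.lstm = nn.LSTM(d_in, cfg.n_units, rng)
        self.drop = nn.Dropout(cfg.dropout_rate,
                               np.random.default_rng(rng.integers(2 ** 31)))
        self.fc = nn.Linear(cfg.n_units, cfg.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        h_last = self.lstm.last_hidden(x)
        return self.fc(self.drop(h_last))


def build_lstm(cfg: LSTMConfig, input_dim: int = 96, seed: int = 0) -> Classifier:
    """Recurrent classifier over (B, T, D) timestep sequences."""
    rng = np.random.default_rng(seed)
    return Classifier("lstm", cfg, nn.Sequential(_LSTMHead(cfg, input_dim, rng)),
                      seed, "frame_sequence")


class _PatchEmbed(nn.Module):
    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator,
                 n_tokens: int):
        super().__init__()
        self.proj = nn.Linear(cfg.T * cfg.C, cfg.d_model, rng)
        self.pe = nn.LearnablePositionalEncoding(n_tokens, cfg.d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pe(self.proj(x))  # X_pos = X_emb + PE


def build_transformer(cfg: TransformerConfig, n_tokens: int = 100,
                      seed: int = 0) -> Classifier:
    """Transformer classifier over (B, n_tokens, T) patch sequences."""
    rng = np.random.default_rng(seed)
    layers: list = [_PatchEmbed(cfg, rng, n_tokens)]
    for _ in range(cfg.L):
        layers.append(nn.TransformerEncoderLayer(
            cfg.d_model, cfg.n_heads, cfg.ffn_dim, cfg.dropout_rate, rng))
    layers += [nn.GlobalAvgPool(axis=1),   # H_pooled from H_final
               nn.Linear(cfg.d_model, cfg.n_classes, rng)]
    return Classifier("transformer", cfg, nn.Sequential(*layers), seed, "patches")


def build_model(arch: str, cfg, seed: int = 0, **kwargs) -> Classifier:
    if arch == "cnn":
        return build_cnn(cfg, seed=seed, **kwargs)
    if arch == "lstm":
        return build_lstm(cfg, seed=seed, **kwargs)
    if arch == "transformer":
        return build_transformer(cfg, seed=seed, **kwargs)
    raise ConfigurationError(f"unknown architecture {arch!r}")
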