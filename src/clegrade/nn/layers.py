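"""Neural-network building blocks on the autodiff core.

Layers follow the batch-first convention used throughout the package:
frame batches are (B, C, H, W), feature sequences are (B, T, D).
Attention masking is additive (-1e9 on padded keys) so that padded
positions can never influence valid ones.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, conv2d

_MASK_FILL = -1e9


class Module:
    """Base class: tracks parameters and sub-modules by attribute."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
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

    def train(self) -> "Module":
        self.training = True
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train()
        return self

    def eval(self) -> "Module":
        self.train()
        self.training = False
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.eval()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def walk(mod: Module, prefix: str) -> None:
            for name, v in mod.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    out[prefix + name] = v.data.copy()
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{name}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{name}.{i}.")

        walk(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        def walk(mod: Module, prefix: str) -> None:
            for name, v in mod.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    v.data[...] = state[prefix + name]
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{name}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{name}.{i}.")

        walk(self, "")


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / math.sqrt(in_dim)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return self.gamma * (centered / (var + self.eps).sqrt()) + self.beta


class Dropout(Module):
    """Inverted dropout driven by an explicit generator for reproducibility."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over the temporal axis.

    With a single token the attention weight is identically 1 and the layer
    reduces to ``W_o(W_v x) + biases`` — a closed form the tests exploit.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"model_dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.w_q = Linear(dim, dim, rng)
        self.w_k = Linear(dim, dim, rng)
        self.w_v = Linear(dim, dim, rng)
        self.w_o = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, key_padding_mask: np.ndarray | None = None) -> Tensor:
        B, T, D = x.shape

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

        q, k, v = split(self.w_q(x)), split(self.w_k(x)), split(self.w_v(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.head_dim))
        if key_padding_mask is not None:
            # mask True = padded; broadcast over heads and query positions
            add = np.where(key_padding_mask[:, None, None, :], _MASK_FILL, 0.0)
            scores = scores + Tensor(add)
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.w_o(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: self-attention and position-wise FFN, each
    wrapped in residual + layer norm."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.norm2 = LayerNorm(dim)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def __call__(self, x: Tensor, key_padding_mask: np.ndarray | None = None) -> Tensor:
        x = self.norm1(x + self.drop1(self.attn(x, key_padding_mask)))
        x = self.norm2(x + self.drop2(self.ff2(self.ff1(x).relu())))
        return x


class TemporalConv1d(Module):
    """1-D convolution along the temporal axis of a (B, T, C) sequence.

    'same' zero padding; an odd kernel keeps outputs centred on their frame.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError(f"conv kernel must be odd and positive, got {kernel}")
        self.kernel = kernel
        self.weight = Tensor(_kaiming(rng, kernel * in_channels,
                                      (kernel, in_channels, out_channels)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        T = x.shape[1]
        half = self.kernel // 2
        xp = x.pad_axis(1, half, half)
        out = None
        for j in range(self.kernel):
            term = xp[:, j:j + T, :] @ self.weight[j]
            out = term if out is None else out + term
        return out + self.bias


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel * kernel
        self.weight = Tensor(_kaiming(rng, fan_in,
                                      (out_channels, in_channels, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


def sinusoidal_positional_encoding(n_positions: int, dim: int) -> np.ndarray:
    """pe[p, 2i] = sin(p / 10000^(2i/D)), pe[p, 2i+1] = cos(p / 10000^(2i/D))."""
    pe = np.zeros((n_positions, dim))
    pos = np.arange(n_positions)[:, None]
    i = np.arange(0, dim, 2)
    div = np.power(10000.0, i / dim)
    pe[:, 0::2] = np.sin(pos / div)
    pe[:, 1::2] = np.cos(pos / div[: pe[:, 1::2].shape[1]])
    return pe
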