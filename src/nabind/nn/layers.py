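"""Neural-network building blocks on top of the autodiff core.

Conventions: activations are ``(batch, length, width)``; ``mask`` is a float
array ``(batch, length)`` with 1 at real residues and 0 at padding.  Padded
keys are excluded from attention by a large negative bias, so padding never
influences outputs at real positions.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concatenate

NEG_INF = -1e9


class Module:
    """Tiny module system: tracks parameters and submodules recursively."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", False)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def set_training(self, flag: bool):
        object.__setattr__(self, "training", flag)
        for m in self._modules.values():
            m.set_training(flag)
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Linear(Module):
    def __init__(self, in_width: int, out_width: int, rng: np.random.Generator):
        super().__init__()
        self.in_width, self.out_width = in_width, out_width
        scale = math.sqrt(2.0 / (in_width + out_width))
        self.weight = parameter(rng.normal(0.0, scale, size=(out_width, in_width)))
        self.bias = parameter(np.zeros(out_width))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose(1, 0) + self.bias


class LayerNorm(Module):
    def __init__(self, width: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = parameter(np.ones(width))
        self.beta = parameter(np.zeros(width))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.binomial(1, keep, size=x.shape) / keep
        return x * Tensor(mask)


class MultiHeadAttention(Module):
    """Scaled dot-product self-attention with ``n_heads`` heads."""

    def __init__(self, width: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if width % n_heads != 0:
            raise ValueError(f"width {width} not divisible by heads {n_heads}")
        self.width, self.n_heads = width, n_heads
        self.head_width = width // n_heads
        self.q_proj = Linear(width, width, rng)
        self.k_proj = Linear(width, width, rng)
        self.v_proj = Linear(width, width, rng)
        self.o_proj = Linear(width, width, rng)

    def _split(self, x: Tensor, batch: int, length: int) -> Tensor:
        return x.reshape(batch, length, self.n_heads, self.head_width).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        batch, length, _ = x.shape
        q = self._split(self.q_proj(x), batch, length)
        k = self._split(self.k_proj(x), batch, length)
        v = self._split(self.v_proj(x), batch, length)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.head_width))
        if mask is not None:
            # 0 where valid, NEG_INF where padded
            bias = (mask[:, None, None, :] - 1.0) * (-NEG_INF)
            scores = scores + Tensor(bias)
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(batch, length, self.width)
        return self.o_proj(out)


class FeedForward(Module):
    def __init__(self, width: int, hidden: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(width, hidden, rng)
        self.fc2 = Linear(hidden, width, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.drop(self.fc1(x).relu()))


class EncoderLayer(Module):
    """Post-norm transformer encoder layer: attention and FFN sub-blocks,
    each wrapped with residual connection, layer norm, and dropout."""

    def __init__(self, width, n_heads, ffn_width, dropout, rng):
        super().__init__()
        self.attn = MultiHeadAttention(width, n_heads, rng)
        self.ffn = FeedForward(width, ffn_width, dropout, rng)
        self.norm1 = LayerNorm(width)
        self.norm2 = LayerNorm(width)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        x = self.norm1(x + self.drop1(self.attn(x, mask)))
        return self.norm2(x + self.drop2(self.ffn(x)))


class StreamRefiner(Module):
    """Intra-modal refinement: one multi-head self-attention layer with a
    residual connection, applied within a single feature stream."""

    def __init__(self, width, n_heads, rng):
        super().__init__()
        self.attn = MultiHeadAttention(width, n_heads, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        return x + self.attn(x, mask)


class MLPHead(Module):
    """Classification head: linear layers with ReLU and dropout, two logits out."""

    def __init__(self, in_width, hidden_widths, dropout, rng, out_width: int = 2):
        super().__init__()
        widths = [in_width, *hidden_widths]
        self.layers = [Linear(widths[i], widths[i + 1], rng) for i in range(len(widths) - 1)]
        self.out = Linear(widths[-1], out_width, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = self.drop(layer(x).relu())
        return self.out(x)


def sinusoidal_encoding(length: int, width: int) -> np.ndarray:
    """Deterministic sinusoidal positional table, positions 0..length-1."""
    position = np.arange(length)[:, None]
    div = np.exp(np.arange(0, width, 2) * (-math.log(10000.0) / width))
    table = np.zeros((length, width))
    table[:, 0::2] = np.sin(position * div)
    table[:, 1::2] = np.cos(position * div[: width // 2])
    return table


def masked_mean_pool(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over unmasked positions; requires at least one per sequence."""
    if (mask.sum(axis=-1) == 0).any():
        raise ValueError("cannot pool a fully masked sequence")
    m = Tensor(mask[..., None])
    total = (x * m).sum(axis=1)
    return total / Tensor(mask.sum(axis=-1, keepdims=True))


__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "Dropout",
    "MultiHeadAttention",
    "FeedForward",
    "EncoderLayer",
    "StreamRefiner",
    "MLPHead",
    "Tensor",
    "concatenate",
    "sinusoidal_encoding",
    "masked_mean_pool",
    "parameter",
]
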