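"""Low-rank adaptation (LoRA) of attention projection matrices.

The update to a frozen weight matrix W (d x k) is reparameterized as a
low-rank product: W_eff = W + (alpha / r) * B @ A with B (d x r) and A
(r x k), r << min(d, k).  A is initialized from a small Gaussian and B to
zero, so immediately after injection the adapted model computes exactly the
same function as the base model.  ``merge_lora`` folds the update back into
W and removes the adapters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .model import FusionModel
from .nn import Linear, Module, MultiHeadAttention, parameter
from .nn.autodiff import Tensor


@dataclass
class LoRAConfig:
    rank: int = 8
    alpha: float = 16.0
    targets: tuple = ("query", "value")
    init_scale: float | None = None  # std of A entries; default 1/rank

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        unknown = set(self.targets) - {"query", "key", "value", "output"}
        if unknown:
            raise ValueError(f"unknown LoRA targets {unknown}")

    @property
    def scaling(self) -> float:
        return self.alpha / self.rank


class LoRALinear(Module):
    """A Linear layer with a frozen base weight plus a trainable low-rank update."""

    def __init__(self, base: Linear, cfg: LoRAConfig, rng: np.random.Generator):
        super().__init__()
        d, k = base.out_width, base.in_width
        if cfg.rank >= min(d, k):
            raise ValueError(f"rank {cfg.rank} must be < min(d={d}, k={k})")
        self.in_width, self.out_width = k, d
        self.scaling = cfg.scaling
        self.weight = base.weight
        self.bias = base.bias
        self.weight.requires_grad = False
        self.bias.requires_grad = False
        std = cfg.init_scale if cfg.init_scale is not None else 1.0 / cfg.rank
        self.lora_a = parameter(rng.normal(0.0, std, size=(cfg.rank, k)))
        self.lora_b = parameter(np.zeros((d, cfg.rank)))

    def __call__(self, x: Tensor) -> Tensor:
        base = x @ self.weight.transpose(1, 0) + self.bias
        update = (x @ self.lora_a.transpose(1, 0)) @ self.lora_b.transpose(1, 0)
        return base + update * self.scaling

    def delta(self) -> np.ndarray:
        return self.scaling * (self.lora_b.data @ self.lora_a.data)

    def merged(self) -> Linear:
        lin = Linear.__new__(Linear)
        Module.__init__(lin)
        lin.in_width, lin.out_width = self.in_width, self.out_width
        lin.weight = parameter(self.weight.data + self.delta())
        lin.weight.requires_grad = False
        lin.bias = self.bias
        return lin


_TARGET_ATTR = {"query": "q_proj", "key": "k_proj", "value": "v_proj", "output": "o_proj"}


def _attention_modules(model: Module) -> Iterable[MultiHeadAttention]:
    for m in model._modules.values():
        if isinstance(m, MultiHeadAttention):
            yield m
        yield from _attention_modules(m)


def inject_lora(model: FusionModel, cfg: LoRAConfig, seed: int = 0) -> FusionModel:
    """Wrap the targeted projections of every attention module in-place.

    Applies to the backbone and the two stream refiners (the stub embedding
    backend has no trainable attention; a finetune-capable pLM backend would
    be adapted through its own integration).
    """
    if has_lora(model):
        raise RuntimeError("model already has LoRA adapters")
    rng = np.random.default_rng(seed)
    n = 0
    for attn in _attention_modules(model):
        for target in cfg.targets:
            attr = _TARGET_ATTR[target]
            setattr(attn, attr, LoRALinear(getattr(attn, attr), cfg, rng))
            n += 1
    if n == 0:
        raise RuntimeError("no attention modules found to adapt")
    model.lora_config = cfg  # plain attribute, not a parameter
    return model


def merge_lora(model: FusionModel) -> FusionModel:
    """Fold every adapter into its base weight (W + scaling * B @ A) and drop it."""
    if not has_lora(model):
        raise RuntimeError("model has no LoRA adapters")
    for attn in _attention_modules(model):
        for attr in _TARGET_ATTR.values():
            layer = getattr(attn, attr)
            if isinstance(layer, LoRALinear):
                setattr(attn, attr, layer.merged())
    model.lora_config = None
    return model


def has_lora(model: Module) -> bool:
    return any(
        isinstance(getattr(attn, attr), LoRALinear)
        for attn in _attention_modules(model)
        for attr in _TARGET_ATTR.values()
    )


def iter_adapters(model: Module) -> Iterable[tuple[str, LoRALinear]]:
    for i, attn in enumerate(_attention_modules(model)):
        for attr in _TARGET_ATTR.values():
            layer = getattr(attn, attr)
            if isinstance(layer, LoRALinear):
                yield f"attn{i}.{attr}", layer


def count_trainable(model: Module) -> int:
    """Number of scalar parameters with gradient updates enabled."""
    return sum(p.data.size for p in model.parameters() if p.requires_grad)


def save_adapters(model: FusionModel, path: str | Path) -> None:
    """Adapter-only checkpoint: A/B matrices plus the LoRA config."""
    import json

    cfg = getattr(model, "lora_config", None)
    if cfg is None:
        raise RuntimeError("model has no LoRA adapters")
    arrays = {}
    for name, layer in iter_adapters(model):
        arrays[f"{name}/A"] = layer.lora_a.data
        arrays[f"{name}/B"] = layer.lora_b.data
    header = json.dumps({"rank": cfg.rank, "alpha": cfg.alpha, "targets": list(cfg.targets)})
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)
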