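"""The multi-modal fusion network.

Three per-residue feature streams — contextual language-model embeddings,
the five Atchley biophysical factors, and the 20 substitution-matrix scores
— are combined as follows.  Each auxiliary stream (Atchley, substitution) is
projected to ``stream_width`` by a linear layer with ReLU and LayerNorm,
receives a fixed sinusoidal positional encoding, and is refined by one
multi-head self-attention layer with a residual connection.  The language
model stream is used as-is.  The three streams are concatenated per residue
(order: pLM, Atchley, substitution) — 1280 + 512 + 512 = 2304 wide under the
defaults — and fed to a stack of transformer encoder layers.  Two MLP heads
produce two-class logits: one per residue (binding-site labeling) and one
per protein after masked mean pooling (binder classification).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import encodings
from .nn import (
    EncoderLayer,
    LayerNorm,
    Linear,
    MLPHead,
    Module,
    StreamRefiner,
    Tensor,
    concatenate,
    masked_mean_pool,
    sinusoidal_encoding,
)
from .plm import EmbeddingBackend
from .records import ProteinRecord

STREAMS = ("plm", "atchley", "blosum")


@dataclass
class ModelConfig:
    plm_width: int = 1280
    stream_width: int = 512
    refine_heads: int = 8
    backbone_layers: int = 2
    backbone_heads: int = 8
    ffn_width: Optional[int] = None  # default 4 x model width
    dropout: float = 0.1
    head_hidden: Sequence[int] = (512, 128)
    pooling: str = "mean"  # or "cls"
    input_proj_width: Optional[int] = None  # optional down-projection before backbone
    streams: Sequence[str] = STREAMS  # streams enabled at the fusion stage
    lora: Optional[dict] = None

    @property
    def fused_width(self) -> int:
        return self.plm_width + 2 * self.stream_width

    @property
    def model_width(self) -> int:
        return self.input_proj_width or self.fused_width

    def __post_init__(self):
        if self.ffn_width is None:
            self.ffn_width = 4 * self.model_width
        unknown = set(self.streams) - set(STREAMS)
        if unknown:
            raise ValueError(f"unknown streams {unknown}")
        if not self.streams:
            raise ValueError("at least one stream must be enabled")
        if self.stream_width % self.refine_heads != 0:
            raise ValueError("refine_heads must divide stream_width")
        if self.model_width % self.backbone_heads != 0:
            raise ValueError("backbone_heads must divide the backbone width")
        if self.pooling not in ("mean", "cls"):
            raise ValueError("pooling must be 'mean' or 'cls'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["head_hidden"] = list(self.head_hidden)
        d["streams"] = list(self.streams)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class PredictionResult:
    protein_id: str
    residue_probabilities: np.ndarray  # (L,) P(binding) per residue
    protein_probability: float
    threshold: float
    residue_calls: np.ndarray = field(init=False)
    protein_call: int = field(init=False)

    def __post_init__(self):
        # inclusive threshold: probability >= threshold is called binding
        self.residue_calls = (self.residue_probabilities >= self.threshold).astype(np.int8)
        self.protein_call = int(self.protein_probability >= self.threshold)


class _StreamProjector(Module):
    """Linear -> ReLU -> LayerNorm projection of a raw prior stream."""

    def __init__(self, in_width: int, out_width: int, rng: np.random.Generator):
        super().__init__()
        self.in_width = in_width
        self.linear = Linear(in_width, out_width, rng)
        self.norm = LayerNorm(out_width)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.linear(x).relu())


class FusionModel(Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.atchley_proj = _StreamProjector(5, c.stream_width, rng)
        self.blosum_proj = _StreamProjector(20, c.stream_width, rng)
        self.atchley_refiner = StreamRefiner(c.stream_width, c.refine_heads, rng)
        self.blosum_refiner = StreamRefiner(c.stream_width, c.refine_heads, rng)
        if c.input_proj_width:
            self.input_proj = Linear(c.fused_width, c.input_proj_width, rng)
        else:
            self.input_proj = None
        self.backbone = [
            EncoderLayer(c.model_width, c.backbone_heads, c.ffn_width, c.dropout, rng)
            for _ in range(c.backbone_layers)
        ]
        self.residue_head = MLPHead(c.model_width, list(c.head_hidden), c.dropout, rng)
        self.protein_head = MLPHead(c.model_width, list(c.head_hidden), c.dropout, rng)

    # -- stream operations (exposed individually for testing) ---------------

    def project_stream(self, block: Tensor | np.ndarray, which: str) -> Tensor:
        proj = {"atchley": self.atchley_proj, "blosum": self.blosum_proj}[which]
        block = block if isinstance(block, Tensor) else Tensor(block)
        if block.shape[-1] != proj.in_width:
            raise ValueError(
                f"{which} stream expects width {proj.in_width}, got {block.shape[-1]}"
            )
        return proj(block)

    @staticmethod
    def add_positional_encoding(block: Tensor) -> Tensor:
        length, width = block.shape[-2], block.shape[-1]
        return block + Tensor(sinusoidal_encoding(length, width))

    def refine_stream(self, block: Tensor, which: str, mask: np.ndarray | None = None) -> Tensor:
        refiner = {"atchley": self.atchley_refiner, "blosum": self.blosum_refiner}[which]
        return refiner(block, mask)

    def fuse_streams(self, plm: Tensor, atchley: Tensor, blosum: Tensor) -> Tensor:
        widths = {t.shape[-2] for t in (plm, atchley, blosum)}
        if len(widths) != 1:
            raise ValueError(f"stream lengths differ: {widths}")
        gates = {s: (1.0 if s in self.config.streams else 0.0) for s in STREAMS}
        return concatenate(
            [plm * gates["plm"], atchley * gates["atchley"], blosum * gates["blosum"]],
            axis=-1,
        )

    def backbone_forward(self, fused: Tensor, mask: np.ndarray) -> Tensor:
        if mask.sum() == 0:
            raise ValueError("all positions masked")
        x = self.input_proj(fused) if self.input_proj is not None else fused
        for layer in self.backbone:
            x = layer(x, mask)
        return x

    # -- full forward --------------------------------------------------------

    def forward(
        self,
        plm_block: np.ndarray,
        atchley_block: np.ndarray,
        blosum_block: np.ndarray,
        mask: np.ndarray,
    ) -> tuple[Tensor, Tensor, Tensor]:
        """Batched forward pass.

        Inputs are (B, L, width) arrays plus a (B, L) validity mask.  Returns
        (hidden, residue_logits, protein_logits).
        """
        a = self.project_stream(Tensor(atchley_block), "atchley")
        b = self.project_stream(Tensor(blosum_block), "blosum")
        a = self.refine_stream(self.add_positional_encoding(a), "atchley", mask)
        b = self.refine_stream(self.add_positional_encoding(b), "blosum", mask)
        fused = self.fuse_streams(Tensor(plm_block), a, b)
        hidden = self.backbone_forward(fused, mask)
        residue_logits = self.residue_head(hidden)
        if self.config.pooling == "cls":
            pooled = hidden[:, 0, :]
        else:
            pooled = masked_mean_pool(hidden, mask)
        protein_logits = self.protein_head(pooled)
        return hidden, residue_logits, protein_logits

    __call__ = forward


def featurize(
    records: Sequence[ProteinRecord],
    backend: EmbeddingBackend,
    atchley: encodings.AtchleyTable | None = None,
    subst: encodings.SubstitutionMatrix | None = None,
) -> list[dict]:
    """Compute the three raw per-residue blocks for each record."""
    atchley = atchley or encodings.load_atchley_table()
    subst = subst or encodings.load_substitution_matrix()
    out = []
    for rec in records:
        out.append(
            {
                "record": rec,
                "plm": backend.embed(rec.sequence),
                "atchley": encodings.encode_atchley(rec.sequence, atchley),
                "blosum": encodings.encode_substitution(rec.sequence, subst),
            }
        )
    return out


def pad_batch(feats: Sequence[dict]) -> dict:
    """Stack variable-length feature dicts into padded (B, L, width) arrays."""
    lengths = [len(f["record"]) for f in feats]
    maxlen = max(lengths)
    batch = {"lengths": lengths, "records": [f["record"] for f in feats]}
    for key, width in (
        ("plm", feats[0]["plm"].shape[1]),
        ("atchley", 5),
        ("blosum", 20),
    ):
        arr = np.zeros((len(feats), maxlen, width))
        for i, f in enumerate(feats):
            arr[i, : lengths[i]] = f[key]
        batch[key] = arr
    mask = np.zeros((len(feats), maxlen))
    for i, n in enumerate(lengths):
        mask[i, :n] = 1.0
    batch["mask"] = mask
    return batch


def predict(
    record: ProteinRecord,
    model: FusionModel,
    backend: EmbeddingBackend,
    task: str = "residue",
    threshold: float = 0.5,
) -> PredictionResult:
    """Run the full pipeline on one record in evaluation mode."""
    if task not in ("protein", "residue"):
        raise ValueError("task must be 'protein' or 'residue'")
    model.set_training(False)
    batch = pad_batch(featurize([record], backend))
    _, residue_logits, protein_logits = model.forward(
        batch["plm"], batch["atchley"], batch["blosum"], batch["mask"]
    )
    res_prob = residue_logits.softmax(axis=-1).data[0, : len(record), 1]
    prot_prob = float(protein_logits.softmax(axis=-1).data[0, 1])
    return PredictionResult(
        protein_id=record.id,
        residue_probabilities=res_prob,
        protein_probability=prot_prob,
        threshold=threshold,
    )


def write_predictions_tsv(results: Sequence[PredictionResult], records, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tresidue\tprobability\tcall\n")
        for res, rec in zip(results, records):
            for i, (p, call) in enumerate(zip(res.residue_probabilities, res.residue_calls)):
                fh.write(f"{res.protein_id}\t{i + 1}\t{rec.sequence[i]}\t{p:.6f}\t{call}\n")


CHECKPOINT_SCHEMA = 1


def _npz_path(path: str | Path) -> str:
    path = str(path)
    return path if path.endswith(".npz") else path + ".npz"


def save_checkpoint(model: FusionModel, path: str | Path) -> str:
    """Single-file archive: JSON config + named parameter arrays."""
    params = {name: p.data for name, p in model.named_parameters()}
    header = json.dumps(
        {"schema": CHECKPOINT_SCHEMA, "config": model.config.to_dict()}
    )
    path = _npz_path(path)
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **params)
    return path


def load_checkpoint(path: str | Path) -> FusionModel:
    with np.load(_npz_path(path)) as archive:
        header = json.loads(bytes(archive["__header__"]).decode())
        if header.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema: {header.get('schema')}")
        model = FusionModel(ModelConfig.from_dict(header["config"]))
        params = dict(model.named_parameters())
        for name in archive.files:
            if name == "__header__":
                continue
            params[name].data = archive[name]
    return model
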