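"""Post-hoc analyses: amino-acid composition at binding sites, enrichment
over background, KL divergence between true and predicted site
distributions, and feature-space export for external t-SNE/UMAP tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import FusionModel, Tensor, featurize, pad_batch
from .nn import masked_mean_pool
from .plm import EmbeddingBackend
from .records import STANDARD_AA, ProteinRecord

DEFAULT_SMOOTHING = 1e-6


@dataclass
class CompositionDistribution:
    probs: np.ndarray  # (20,) over STANDARD_AA
    n_samples: int
    smoothing: float = DEFAULT_SMOOTHING

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (20,):
            raise ValueError("composition must cover the 20 standard letters")
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-9) or (self.probs < 0).any():
            raise ValueError("composition must be a probability distribution")

    def __getitem__(self, aa: str) -> float:
        return float(self.probs[STANDARD_AA.index(aa)])


def site_composition(
    records: Sequence[ProteinRecord],
    calls: Sequence[np.ndarray],
    smoothing: float = DEFAULT_SMOOTHING,
) -> CompositionDistribution:
    """Letter frequencies among called positions, additively smoothed."""
    counts = np.zeros(20)
    index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    n = 0
    for rec, call in zip(records, calls):
        call = np.asarray(call)
        if call.shape != (len(rec),):
            raise ValueError(f"calls misaligned for record {rec.id}")
        for aa, c in zip(rec.sequence, call):
            if c and aa in index:
                counts[index[aa]] += 1
                n += 1
    if n == 0:
        raise ValueError("no called positions")
    probs = counts + smoothing
    return CompositionDistribution(probs=probs / probs.sum(), n_samples=n, smoothing=smoothing)


def background_composition(
    records: Sequence[ProteinRecord], smoothing: float = DEFAULT_SMOOTHING
) -> CompositionDistribution:
    """Whole-sequence composition (every position 'called')."""
    return site_composition(
        records, [np.ones(len(r), dtype=int) for r in records], smoothing=smoothing
    )


def enrichment(
    site: CompositionDistribution, background: CompositionDistribution
) -> dict[str, float]:
    """Per-letter log2(site/background); smoothing guarantees positivity."""
    ratios = np.log2(site.probs / background.probs)
    return {aa: float(r) for aa, r in zip(STANDARD_AA, ratios)}


def top_enriched(enrich: dict[str, float], k: int = 3) -> list[str]:
    return sorted(enrich, key=enrich.get, reverse=True)[:k]


def kl_divergence(
    p: CompositionDistribution,
    q: CompositionDistribution,
    direction: str = "forward",
) -> float:
    """KL divergence in nats.  ``forward`` is KL(p || q) = sum p ln(p/q);
    ``reverse`` swaps the arguments."""
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    a, b = (p.probs, q.probs) if direction == "forward" else (q.probs, p.probs)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("distributions must be strictly positive (apply smoothing)")
    return float(np.sum(a * np.log(a / b)))


def export_features(
    model: FusionModel,
    records: Sequence[ProteinRecord],
    backend: EmbeddingBackend,
    stage: str = "post",
    level: str = "residue",
    path: str | Path | None = None,
    fmt: str = "tsv",
) -> np.ndarray:
    """Per-residue (or pooled per-protein) feature rows with class labels.

    ``stage`` selects the fused input features (``pre``) or the backbone
    hidden states (``post``).  Written as TSV or HDF5 when ``path`` is given;
    the labeled matrix is returned either way for external embedding tools.
    """
    if stage not in ("pre", "post"):
        raise ValueError("stage must be 'pre' or 'post'")
    if level not in ("residue", "protein"):
        raise ValueError("level must be 'residue' or 'protein'")
    model.set_training(False)
    rows, labels = [], []
    for feat in featurize(records, backend):
        batch = pad_batch([feat])
        rec = feat["record"]
        a = model.project_stream(Tensor(batch["atchley"]), "atchley")
        b = model.project_stream(Tensor(batch["blosum"]), "blosum")
        a = model.refine_stream(model.add_positional_encoding(a), "atchley", batch["mask"])
        b = model.refine_stream(model.add_positional_encoding(b), "blosum", batch["mask"])
        fused = model.fuse_streams(Tensor(batch["plm"]), a, b)
        feats_t = fused if stage == "pre" else model.backbone_forward(fused, batch["mask"])
        if level == "residue":
            if rec.residue_labels is None:
                raise ValueError(f"record {rec.id} lacks residue labels")
            rows.append(feats_t.data[0, : len(rec)])
            labels.append(rec.residue_labels)
        else:
            pooled = masked_mean_pool(feats_t, batch["mask"])
            rows.append(pooled.data)
            labels.append([rec.protein_label if rec.protein_label is not None else -1])
    matrix = np.concatenate(rows, axis=0)
    labels = np.concatenate(labels).astype(int)
    out = np.column_stack([labels, matrix])
    if path is not None:
        if fmt == "tsv":
            header = "label\t" + "\t".join(f"f{i}" for i in range(matrix.shape[1]))
            np.savetxt(path, out, delimiter="\t", header=header, comments="")
        elif fmt == "hdf5":
            import h5py

            with h5py.File(path, "w") as fh:
                fh.create_dataset("features", data=matrix)
                fh.create_dataset("labels", data=labels)
        else:
            raise ValueError("fmt must be 'tsv' or 'hdf5'")
    return out
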