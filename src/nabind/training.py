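"""End-to-end training: cross-entropy loss, AdamW, seeded repetitions, and
stream-ablation experiment configs.

Training is deterministic given the config seed, which fixes weight
initialization, the validation split, data shuffling, and dropout draws.
Residue-task losses are averaged over real (unpadded) positions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import metrics
from .lora import LoRAConfig, inject_lora
from .model import STREAMS, FusionModel, ModelConfig, featurize, pad_batch
from .nn import AdamW, Tensor
from .plm import EmbeddingBackend, get_backend
from .records import ProteinRecord


@dataclass
class TrainConfig:
    task: str = "residue"  # or "protein"
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    class_weights: Optional[tuple[float, float]] = None
    seed: int = 0
    streams: Sequence[str] = STREAMS
    model: ModelConfig = field(default_factory=ModelConfig)
    lora: Optional[LoRAConfig] = None
    val_fraction: float = 0.1
    backend_name: str = "stub"
    backend_width: Optional[int] = None  # default: model.plm_width
    backend_seed: int = 0  # embeddings are data, not model state: fixed by default

    def __post_init__(self):
        if self.task not in ("protein", "residue"):
            raise ValueError("task must be 'protein' or 'residue'")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch size and learning rate must be positive")
        if not self.streams:
            raise ValueError("at least one stream must be enabled")

    def make_backend(self) -> EmbeddingBackend:
        width = self.backend_width or self.model.plm_width
        if self.backend_name == "stub":
            return get_backend("stub", width=width, seed=self.backend_seed)
        return get_backend(self.backend_name, width=width)

    def make_model(self) -> FusionModel:
        model_cfg = replace(self.model, streams=tuple(self.streams))
        model = FusionModel(model_cfg, seed=self.seed)
        if self.lora is not None:
            inject_lora(model, self.lora, seed=self.seed)
        return model


@dataclass
class RunHistory:
    seed: int
    epoch_losses: list[float] = field(default_factory=list)
    val_metrics: list[dict] = field(default_factory=list)
    initial_loss: Optional[float] = None
    final_report: Optional[metrics.MetricReport] = None

    def check(self):
        if not all(np.isfinite(x) for x in self.epoch_losses):
            raise RuntimeError("non-finite training loss")


def cross_entropy_loss(
    logits: Tensor,
    labels: np.ndarray,
    mask: np.ndarray | None = None,
    class_weights: Optional[tuple[float, float]] = None,
) -> Tensor:
    """Mean two-class cross-entropy; padded positions excluded via ``mask``."""
    logp = logits.log_softmax(axis=-1)
    onehot = np.stack([(labels == 0), (labels == 1)], axis=-1).astype(float)
    if class_weights is not None:
        w = np.where(labels == 1, class_weights[1], class_weights[0]).astype(float)
    else:
        w = np.ones(labels.shape, dtype=float)
    if mask is not None:
        w = w * mask
    picked = (logp * Tensor(onehot)).sum(axis=-1)
    total = (picked * Tensor(w)).sum() * -1.0
    return total / Tensor(np.array(w.sum()))


def _batch_targets(batch: dict, task: str) -> tuple[np.ndarray, np.ndarray | None]:
    if task == "residue":
        maxlen = batch["mask"].shape[1]
        labels = np.zeros((len(batch["records"]), maxlen), dtype=int)
        for i, rec in enumerate(batch["records"]):
            if rec.residue_labels is None:
                raise ValueError(f"record {rec.id} lacks residue labels")
            labels[i, : len(rec)] = rec.residue_labels
        return labels, batch["mask"]
    labels = []
    for rec in batch["records"]:
        if rec.protein_label is None:
            raise ValueError(f"record {rec.id} lacks a protein label")
        labels.append(rec.protein_label)
    return np.asarray(labels, dtype=int), None


def _collect_scores(
    model: FusionModel, feats: list[dict], task: str, batch_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation-mode scores and labels, concatenated over the dataset."""
    model.set_training(False)
    scores, labels = [], []
    for start in range(0, len(feats), batch_size):
        batch = pad_batch(feats[start : start + batch_size])
        _, residue_logits, protein_logits = model.forward(
            batch["plm"], batch["atchley"], batch["blosum"], batch["mask"]
        )
        if task == "residue":
            probs = residue_logits.softmax(axis=-1).data[..., 1]
            for i, rec in enumerate(batch["records"]):
                scores.append(probs[i, : len(rec)])
                labels.append(rec.residue_labels)
        else:
            scores.append(protein_logits.softmax(axis=-1).data[:, 1])
            labels.append([rec.protein_label for rec in batch["records"]])
    return np.concatenate(scores), np.concatenate(labels).astype(int)


def split_validation(
    records: Sequence[ProteinRecord], fraction: float, seed: int
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Seeded split by protein; validation gets ``fraction`` of the records."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_val = max(1, int(round(fraction * len(records)))) if fraction > 0 else 0
    val_idx = set(order[:n_val].tolist())
    train = [records[i] for i in range(len(records)) if i not in val_idx]
    val = [records[i] for i in range(len(records)) if i in val_idx]
    return train, val


def train(
    model: FusionModel | None,
    data: Sequence[ProteinRecord],
    cfg: TrainConfig,
    val_data: Optional[Sequence[ProteinRecord]] = None,
) -> tuple[FusionModel, RunHistory]:
    """Train on ``data``; if ``val_data`` is None, a seeded fraction of
    ``data`` is held out for per-epoch validation metrics."""
    if model is None:
        model = cfg.make_model()
    backend = cfg.make_backend()
    if val_data is None and cfg.val_fraction > 0 and len(data) > 1:
        data, val_data = split_validation(data, cfg.val_fraction, cfg.seed)
    feats = featurize(data, backend)
    val_feats = featurize(val_data, backend) if val_data else None

    trainable = [p for p in model.parameters() if p.requires_grad]
    opt = AdamW(
        trainable, lr=cfg.learning_rate, weight_decay=cfg.weight_decay
    )
    rng = np.random.default_rng(cfg.seed)
    history = RunHistory(seed=cfg.seed)
    for epoch in range(cfg.epochs):
        model.set_training(True)
        order = rng.permutation(len(feats))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = pad_batch([feats[i] for i in idx])
            labels, mask = _batch_targets(batch, cfg.task)
            _, residue_logits, protein_logits = model.forward(
                batch["plm"], batch["atchley"], batch["blosum"], batch["mask"]
            )
            logits = residue_logits if cfg.task == "residue" else protein_logits
            loss = cross_entropy_loss(logits, labels, mask, cfg.class_weights)
            if history.initial_loss is None:
                history.initial_loss = float(loss.data)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.epoch_losses.append(float(np.mean(losses)))
        if val_feats:
            scores, truth = _collect_scores(model, val_feats, cfg.task, cfg.batch_size)
            report = metrics.evaluate_binary(scores, truth, seed=cfg.seed)
            history.val_metrics.append(report.to_dict())
            history.final_report = report
        history.check()
    model.set_training(False)
    return model, history


def evaluate_model(
    model: FusionModel,
    records: Sequence[ProteinRecord],
    cfg: TrainConfig,
    threshold: float = 0.5,
) -> metrics.MetricReport:
    feats = featurize(records, cfg.make_backend())
    scores, truth = _collect_scores(model, feats, cfg.task, cfg.batch_size)
    return metrics.evaluate_binary(scores, truth, threshold=threshold, seed=cfg.seed)


def repeat_runs(
    data: Sequence[ProteinRecord],
    cfg: TrainConfig,
    seeds: Sequence[int],
    test_data: Optional[Sequence[ProteinRecord]] = None,
) -> tuple[list[RunHistory], list[metrics.MetricReport]]:
    """Independent seeded repetitions (the benchmark protocol uses 10).

    Each run reseeds weight initialization, the split, shuffling and dropout;
    per-seed metric reports are retained for rank-based model comparison.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    histories, reports = [], []
    for seed in seeds:
        run_cfg = replace(cfg, seed=int(seed))
        model, history = train(None, list(data), run_cfg, val_data=test_data)
        if test_data is not None:
            report = evaluate_model(model, test_data, run_cfg)
        elif history.final_report is not None:
            report = history.final_report
        else:
            report = evaluate_model(model, list(data), run_cfg)
        histories.append(history)
        reports.append(report)
    return histories, reports


def small_config(task: str = "residue", seed: int = 0, **overrides) -> TrainConfig:
    """Desk-scale configuration: a narrow model (16/16/16 stream widths,
    one backbone layer) trained for 8 epochs at lr 3e-3.  Used by the demo
    workflows and the synthetic-learnability checks; finishes in seconds on
    one CPU while leaving the architecture identical in shape to the full
    default."""
    model = ModelConfig(
        plm_width=16,
        stream_width=16,
        refine_heads=2,
        backbone_layers=1,
        backbone_heads=2,
        ffn_width=64,
        head_hidden=(32,),
        dropout=0.1,
    )
    cfg = TrainConfig(
        task=task,
        epochs=8,
        batch_size=8,
        learning_rate=3e-3,
        model=model,
        seed=seed,
        val_fraction=0.0,
    )
    return replace(cfg, **overrides) if overrides else cfg


def ablate_streams(cfg: TrainConfig, remove: set[str] | Sequence[str]) -> TrainConfig:
    """Return a config with the named streams zeroed at the fusion stage."""
    remove = set(remove)
    unknown = remove - set(STREAMS)
    if unknown:
        raise ValueError(f"unknown streams {unknown}")
    remaining = tuple(s for s in cfg.streams if s not in remove)
    if not remaining:
        raise ValueError("cannot remove every stream")
    return replace(cfg, streams=remaining)


def reports_to_samples(reports: Sequence[metrics.MetricReport]) -> dict[str, list[float]]:
    """Per-metric samples across seeds, for Mann-Whitney comparison."""
    out: dict[str, list[float]] = {}
    for name in ("precision", "recall", "f1", "mcc", "auroc"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if vals:
            out[name] = [float(v) for v in vals]
    return out
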