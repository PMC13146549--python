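"""Evaluation metrics and the statistical comparison protocol.

Binary-classification metrics follow the standard confusion-count formulas
(precision, recall, F1, MCC); AUROC is computed from average ranks, which
equals the probability that a random positive outscores a random negative
with ties counted half.  Model comparisons use the two-sided Mann-Whitney U
test over per-seed metric samples — exact enumeration for small samples,
tie-corrected normal approximation otherwise — with Benjamini-Hochberg
adjustment across metrics and a 0.05 significance threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_MW_LIMIT = 12  # n_x + n_y at or below this: exact enumeration


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    precision: float
    recall: float
    f1: float
    mcc: float
    auroc: Optional[float]
    threshold: float = 0.5
    n_positives: int = 0
    n_total: int = 0
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
            "auroc": self.auroc,
            "threshold": self.threshold,
            "n_positives": self.n_positives,
            "n_total": self.n_total,
            "seed": self.seed,
        }


def confusion(pred: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    return ConfusionCounts(
        tp=int(((pred == 1) & (truth == 1)).sum()),
        fp=int(((pred == 1) & (truth == 0)).sum()),
        tn=int(((pred == 0) & (truth == 0)).sum()),
        fn=int(((pred == 0) & (truth == 1)).sum()),
    )


def _guarded(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; returning 0")
        return 0.0
    return num / den


def precision(c: ConfusionCounts) -> float:
    return _guarded(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _guarded(c.tp, c.tp + c.fn, "recall")


def f1(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    return _guarded(2.0 * p * r, p + r, "F1")


def mcc(c: ConfusionCounts) -> float:
    num = c.tp * c.tn - c.fn * c.fp
    den = math.sqrt(
        float(c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fn) * (c.tn + c.fp)
    )
    return _guarded(num, den, "MCC")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUROC with midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("score/label length mismatch")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate_binary(
    scores: Sequence[float],
    truth: Sequence[int],
    threshold: float = 0.5,
    seed: Optional[int] = None,
) -> MetricReport:
    """Threshold scores (inclusive: score >= threshold is a positive call)
    and assemble the full metric report."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    calls = (scores >= threshold).astype(int)
    c = confusion(calls, truth)
    both_classes = 0 < truth.sum() < truth.size
    return MetricReport(
        precision=precision(c),
        recall=recall(c),
        f1=f1(c),
        mcc=mcc(c),
        auroc=auroc(scores, truth) if both_classes else None,
        threshold=threshold,
        n_positives=int(truth.sum()),
        n_total=int(truth.size),
        seed=seed,
    )


def mcc_maximizing_threshold(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Pick the candidate threshold (observed score values) maximizing MCC."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    best_t, best_m = 0.5, -2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t in np.unique(scores):
            m = mcc(confusion((scores >= t).astype(int), truth))
            if m > best_m:
                best_t, best_m = float(t), m
    return best_t


def relative_improvement(a: float, b: float) -> float:
    """Percent improvement of ``a`` over baseline ``b``: 100*(a-b)/b,
    rounded half-up to two decimals at this reporting boundary."""
    if b <= 0:
        raise ValueError("baseline must be > 0")
    import decimal

    pct = decimal.Decimal(str(100.0 * (a - b) / b)).quantize(
        decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP
    )
    return float(pct)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    For n_x + n_y <= 12 the p-value is computed by exact enumeration of all
    label assignments (midranks for ties): p = min(1, 2*min(P(U<=u), P(U>=u))).
    Larger samples use the tie-corrected normal approximation.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    nx, ny = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    if nx + ny <= EXACT_MW_LIMIT:
        us = []
        for idx in combinations(range(nx + ny), nx):
            us.append(ranks[list(idx)].sum() - nx * (nx + 1) / 2.0)
        us = np.asarray(us)
        lo = (us <= u_obs + 1e-12).mean()
        hi = (us >= u_obs - 1e-12).mean()
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return u_obs, float(p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotone and capped at 1."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if ((pvals < 0) | (pvals > 1)).any() or not np.isfinite(pvals).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    return adjusted


@dataclass
class ComparisonReport:
    """Per-metric comparison of a model against a baseline over seeded runs."""

    metrics: list[str]
    improvement_pct: list[float]
    u_statistics: list[float]
    p_raw: list[float]
    p_adjusted: list[float] = field(default_factory=list)
    significant: list[bool] = field(default_factory=list)
    alpha: float = 0.05

    def to_rows(self) -> list[dict]:
        return [
            {
                "metric": m,
                "improvement_pct": imp,
                "U": u,
                "p_raw": pr,
                "p_adjusted": pa,
                "significant": sig,
            }
            for m, imp, u, pr, pa, sig in zip(
                self.metrics,
                self.improvement_pct,
                self.u_statistics,
                self.p_raw,
                self.p_adjusted,
                self.significant,
            )
        ]


def compare_models(
    model_runs: dict[str, Sequence[float]],
    baseline_runs: dict[str, Sequence[float]],
    alpha: float = 0.05,
) -> ComparisonReport:
    """Compare per-seed metric samples of two models metric-by-metric."""
    metrics = [m for m in model_runs if m in baseline_runs]
    if not metrics:
        raise ValueError("no shared metrics to compare")
    improvements, us, ps = [], [], []
    for m in metrics:
        a = np.asarray(model_runs[m], dtype=float)
        b = np.asarray(baseline_runs[m], dtype=float)
        improvements.append(relative_improvement(float(a.mean()), float(b.mean())))
        u, p = mann_whitney_u(a, b)
        us.append(u)
        ps.append(p)
    adjusted = bh_adjust(ps)
    return ComparisonReport(
        metrics=metrics,
        improvement_pct=improvements,
        u_statistics=us,
        p_raw=ps,
        p_adjusted=list(map(float, adjusted)),
        significant=[bool(p <= alpha) for p in adjusted],
        alpha=alpha,
    )
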