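"""Evaluation metrics: confusion counts, threshold metrics, ROC/AUC and
benchmark overlap.

AUC is computed tie-aware: the ROC curve groups tied scores into single
threshold steps and the trapezoid area then equals the Mann-Whitney
statistic (concordant pairs + half ties) / (#pos * #neg), which makes the
value unique under ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionTable",
    "ScalarMetrics",
    "confusion",
    "scalar_metrics",
    "roc_auc",
    "average_precision",
    "benchmark_overlap",
]


@dataclass(frozen=True)
class ConfusionTable:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.FP + self.TN + self.FN == 0:
            raise ValueError("empty confusion table")


@dataclass(frozen=True)
class ScalarMetrics:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    flagged: frozenset[str]  # metrics whose denominator was zero (reported as 0)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
        }


def confusion(y_true, y_pred) -> ConfusionTable:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("inputs must be binary")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return ConfusionTable(TP=tp, FP=fp, TN=tn, FN=fn)


def scalar_metrics(ct: ConfusionTable) -> ScalarMetrics:
    """Accuracy, precision, recall, specificity, F1.

    Zero-denominator metrics are reported as 0 and named in ``flagged`` —
    a convention that keeps averaging over many runs well-defined.
    """
    flagged: set[str] = set()

    def safe(num: int, den: int, name: str) -> float:
        if den == 0:
            flagged.add(name)
            return 0.0
        return num / den

    total = ct.TP + ct.FP + ct.TN + ct.FN
    accuracy = (ct.TP + ct.TN) / total
    precision = safe(ct.TP, ct.TP + ct.FP, "precision")
    recall = safe(ct.TP, ct.TP + ct.FN, "recall")
    specificity = safe(ct.TN, ct.TN + ct.FP, "specificity")
    if precision + recall == 0:
        flagged.add("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ScalarMetrics(accuracy, precision, recall, specificity, f1, frozenset(flagged))


def roc_auc(y_true, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep over unique scores plus trapezoid AUC.

    Returns (fpr, tpr, auc). Tied scores collapse into one curve vertex, so
    the trapezoid area equals the normalized Mann-Whitney U statistic.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.shape != scores.shape:
        raise ValueError("length mismatch")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = y_true[order]
    # indices where the score value changes: curve vertices
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    idx = np.r_[distinct, s.size - 1]
    tps = np.cumsum(t == 1)[idx]
    fps = np.cumsum(t == 0)[idx]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def average_precision(y_true, scores) -> float:
    """Precision-recall trapezoid area (descending-threshold sweep)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int((y_true == 1).sum())
    if n_pos == 0:
        raise ValueError("no positives")
    order = np.argsort(-scores, kind="stable")
    t = y_true[order]
    s = scores[order]
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    idx = np.r_[distinct, s.size - 1]
    tps = np.cumsum(t == 1)[idx].astype(float)
    fps = np.cumsum(t == 0)[idx].astype(float)
    precision = tps / (tps + fps)
    recall = tps / n_pos
    precision = np.r_[1.0, precision]
    recall = np.r_[0.0, recall]
    return float(np.trapezoid(precision, recall))


def benchmark_overlap(ranked, bench, top_n: int) -> float:
    """Fraction of the top_n ranked genes that belong to the benchmark set."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    genes = [g for g, _ in ranked.items] if hasattr(ranked, "items") else list(ranked)
    if top_n > len(genes):
        raise ValueError("top_n exceeds ranked list length")
    bench_genes = bench.genes if hasattr(bench, "genes") else set(bench)
    top = genes[:top_n]
    return sum(g in bench_genes for g in top) / top_n
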