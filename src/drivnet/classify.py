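"""Gene-level driver classification on embedding vectors.

Every embedded gene is one observation: features are its embedding vector,
label 1 if the gene is in the benchmark driver set, 0 otherwise (the
standard unlabeled-as-negative convention — there is no curated negative
set). The class imbalance is handled by undersampling the majority class;
evaluation repeats `n_undersamples` balanced draws x `n_repeats` stratified
80/20 splits (10 x 10 = 100 runs by default) and averages per-run metrics.

Five classifier families are supported: KNN, logistic regression, SVM,
random forest, and gradient-boosted trees (XGBoost, whose regularized
objective penalizes leaf count and squared leaf weights).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .metrics import confusion, roc_auc, scalar_metrics
from .net_io import BenchmarkGeneSet, EmbeddingTable

log = logging.getLogger("drivnet")

__all__ = [
    "MODEL_NAMES",
    "LabeledDataset",
    "CVResult",
    "RankedGeneList",
    "build_dataset",
    "undersample",
    "run_repeated_eval",
    "train_final_and_rank",
    "consensus_novel_genes",
]

MODEL_NAMES = ("knn", "lr", "svm", "rf", "xgbt")

DEFAULT_N_UNDERSAMPLES = 10
DEFAULT_N_REPEATS = 10


@dataclass
class LabeledDataset:
    gene_ids: list[str]
    features: np.ndarray  # (n_genes, d)
    labels: np.ndarray    # binary

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.shape[0] != len(self.gene_ids) or self.labels.shape[0] != len(self.gene_ids):
            raise ValueError("rows of features/labels must align with gene_ids")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.labels.min() == self.labels.max():
            raise ValueError("dataset needs at least one gene per class")

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == 0).sum())


@dataclass
class CVResult:
    """Per-run metric rows plus their arithmetic mean/std summary."""

    model: str
    runs: list[dict[str, float]]
    seed: int
    fold_scheme: str

    def summary(self) -> dict[str, dict[str, float]]:
        keys = self.runs[0].keys()
        out: dict[str, dict[str, float]] = {}
        for k in keys:
            vals = np.array([r[k] for r in self.runs])
            out[k] = {"mean": float(vals.mean()), "std": float(vals.std())}
        return out

    def mean(self, metric: str) -> float:
        return float(np.mean([r[metric] for r in self.runs]))


@dataclass
class RankedGeneList:
    """(gene, score) pairs sorted by non-increasing score, ties by gene id."""

    items: list[tuple[str, float]]

    def __post_init__(self) -> None:
        self.items = sorted(self.items, key=lambda t: (-t[1], t[0]))

    def top(self, n: int) -> list[str]:
        return [g for g, _ in self.items[:n]]

    def rank_of(self, gene: str) -> int:
        for r, (g, _) in enumerate(self.items, start=1):
            if g == gene:
                return r
        raise KeyError(gene)


def _make_model(name: str, seed: int, n_train: int):
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=min(5, max(1, n_train - 1)))
    if name == "lr":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "svm":
        return SVC(probability=True, random_state=seed)
    if name == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if name == "xgbt":
        return XGBClassifier(
            random_state=seed, n_jobs=1, tree_method="hist",
            eval_metric="logloss", verbosity=0,
        )
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def build_dataset(emb: EmbeddingTable, bench: BenchmarkGeneSet) -> LabeledDataset:
    """One row per embedded gene, label 1 iff it is a benchmark driver."""
    if not emb.gene_ids:
        raise ValueError("empty embedding table")
    labels = np.array([1 if g in bench.genes else 0 for g in emb.gene_ids], dtype=np.int64)
    missing = len(bench.genes) - int(labels.sum())
    if missing:
        log.info("build_dataset: %d benchmark genes have no embedding (ignored)", missing)
    if labels.sum() == 0:
        raise ValueError("no benchmark gene has an embedding")
    if labels.sum() == labels.size:
        raise ValueError("no negative (non-benchmark) genes among embeddings")
    return LabeledDataset(list(emb.gene_ids), emb.vectors.copy(), labels)


def undersample(ds: LabeledDataset, seed: int) -> LabeledDataset:
    """Subsample the majority class without replacement to the minority count."""
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(ds.labels == 1)
    neg = np.flatnonzero(ds.labels == 0)
    minority, majority = (pos, neg) if pos.size <= neg.size else (neg, pos)
    kept_majority = rng.choice(majority, size=minority.size, replace=False)
    keep = np.sort(np.concatenate([minority, kept_majority]))
    return LabeledDataset(
        [ds.gene_ids[i] for i in keep], ds.features[keep], ds.labels[keep]
    )


def _one_run(ds: LabeledDataset, model_name: str, run_seed: int) -> dict[str, float]:
    for attempt in range(10):
        s = run_seed + attempt
        X_tr, X_te, y_tr, y_te = train_test_split(
            ds.features, ds.labels, test_size=0.2, random_state=s, stratify=ds.labels
        )
        if y_te.min() != y_te.max() and y_tr.min() != y_tr.max():
            break
        log.info("degenerate fold at seed %d; redrawing", s)
    model = _make_model(model_name, s, len(y_tr))
    model.fit(X_tr, y_tr)
    y_pred = model.predict(X_te)
    if hasattr(model, "predict_proba"):
        score = model.predict_proba(X_te)[:, 1]
    else:
        score = model.decision_function(X_te)
    sm = scalar_metrics(confusion(y_te, y_pred))
    _, _, auc = roc_auc(y_te, score)
    row = sm.as_dict()
    row["roc_auc"] = auc
    return row


def run_repeated_eval(
    ds: LabeledDataset,
    model: str,
    n_repeats: int = DEFAULT_N_REPEATS,
    n_undersamples: int = DEFAULT_N_UNDERSAMPLES,
    seed: int = 0,
) -> CVResult:
    """Repeated undersampled holdout evaluation.

    Each run draws one balanced undersample and one stratified 80/20 split,
    fits the model and scores the held-out 20%. Defaults give
    10 undersamples x 10 splits = 100 runs; the summary is the arithmetic
    mean of per-run metrics.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}")
    if n_repeats < 1 or n_undersamples < 1:
        raise ValueError("n_repeats and n_undersamples must be >= 1")
    runs: list[dict[str, float]] = []
    for u in range(n_undersamples):
        balanced = undersample(ds, seed=seed * 1009 + u)
        for r in range(n_repeats):
            run_seed = (seed * 100003 + u * 211 + r * 7 + 1) % (2**31)
            runs.append(_one_run(balanced, model, run_seed))
    return CVResult(model=model, runs=runs, seed=seed,
                    fold_scheme=f"{n_undersamples}x{n_repeats} undersample/holdout(80/20)")


def train_final_and_rank(ds: LabeledDataset, model: str, seed: int = 0) -> RankedGeneList:
    """Fit on one balanced draw and score every gene by P(driver)."""
    balanced = undersample(ds, seed=seed)
    clf = _make_model(model, seed, len(balanced.labels))
    clf.fit(balanced.features, balanced.labels)
    if hasattr(clf, "predict_proba"):
        scores = clf.predict_proba(ds.features)[:, 1]
    else:  # pragma: no cover - all five families expose predict_proba
        raw = clf.decision_function(ds.features)
        scores = 1.0 / (1.0 + np.exp(-raw))
    return RankedGeneList(list(zip(ds.gene_ids, map(float, scores))))


def consensus_novel_genes(
    ranked_lists: dict[str, RankedGeneList] | list[RankedGeneList],
    bench: BenchmarkGeneSet,
    top_n: int,
) -> list[str]:
    """Genes in every model's top_n that are not already benchmark drivers,
    ordered by mean rank across the lists (tie-break by gene id)."""
    lists = list(ranked_lists.values()) if isinstance(ranked_lists, dict) else list(ranked_lists)
    if len(lists) < 2:
        raise ValueError("consensus needs at least two ranked lists")
    common = set(lists[0].top(top_n))
    for rl in lists[1:]:
        common &= set(rl.top(top_n))
    common -= set(bench.genes)
    if not common:
        return []
    mean_rank = {g: float(np.mean([rl.rank_of(g) for rl in lists])) for g in common}
    return sorted(common, key=lambda g: (mean_rank[g], g))
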