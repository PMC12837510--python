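"""Classification metrics, multi-seed aggregation, and the forgetting probe.

Metrics are accuracy under argmax, rank-based AUC (macro one-vs-rest for
more than two classes), and macro-averaged F1.  The forgetting probe
quantifies how much first-domain knowledge a checkpoint retains after later
stages: a frozen-encoder logistic probe on token-mean pooled features is
trained on first-domain labeled data and evaluated on a held-out split; its
AUC is the retention score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score

from .exceptions import InvalidInputError
from .mae import Checkpoint
from .pipeline import _pixels

__all__ = [
    "MetricsRecord",
    "SeedAggregate",
    "compute_metrics",
    "aggregate_seeds",
    "format_mean_std",
    "forgetting_probe",
]


@dataclass(frozen=True)
class MetricsRecord:
    acc: float
    auc: float
    f1: float
    n_test: int
    class_count: int
    seed: int | None = None


@dataclass(frozen=True)
class SeedAggregate:
    mean: dict[str, float]
    std: dict[str, float]
    seeds: tuple


def compute_metrics(y_true, scores, seed: int | None = None) -> MetricsRecord:
    """ACC / AUC / macro-F1 from per-class probability scores.

    ``scores`` is (n, k) with rows summing to 1; binary AUC uses the
    positive-class column, multiclass AUC is macro one-vs-rest.  Ties in the
    ranking get mid-rank half credit.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise InvalidInputError("scores must be (n_samples, n_classes)")
    classes = np.unique(y_true)
    if classes.size < 2:
        raise InvalidInputError("AUC undefined with a single class present")
    labels = np.sort(classes)
    y_idx = np.searchsorted(labels, y_true)
    acc = float(np.mean(scores.argmax(axis=1) == y_idx))
    if labels.size == 2:
        auc = float(roc_auc_score(y_idx, scores[:, 1]))
    else:
        auc = float(roc_auc_score(y_idx, scores, multi_class="ovr", average="macro"))
    f1 = float(f1_score(y_idx, scores.argmax(axis=1), average="macro"))
    return MetricsRecord(
        acc=acc, auc=auc, f1=f1, n_test=int(y_true.shape[0]),
        class_count=int(labels.size), seed=seed,
    )


def aggregate_seeds(records: list[MetricsRecord]) -> SeedAggregate:
    """Arithmetic mean and population standard deviation per metric."""
    if not records:
        raise InvalidInputError("no records to aggregate")
    out_mean, out_std = {}, {}
    for name in ("acc", "auc", "f1"):
        vals = np.array([getattr(r, name) for r in records], dtype=np.float64)
        out_mean[name] = float(vals.mean())
        out_std[name] = float(vals.std())  # population (ddof=0)
    return SeedAggregate(
        mean=out_mean, std=out_std, seeds=tuple(r.seed for r in records)
    )


def format_mean_std(mean: float, std: float) -> str:
    """`0.873±0.030`-style fixed three-decimal formatting."""
    return f"{mean:.3f}±{std:.3f}"


def forgetting_probe(
    ckpt: Checkpoint,
    train_data: list[tuple],
    test_data: list[tuple],
    seed: int = 0,
) -> MetricsRecord:
    """Retention of earlier-domain knowledge, as frozen-probe performance.

    A logistic-regression probe on token-mean pooled encoder features is
    trained on labeled data from the earlier domain and scored on its test
    split.  Probing the original stage-1 checkpoint gives the retention
    reference point; probing later checkpoints measures forgetting.
    """
    x_tr = _pooled(ckpt, [im for im, _ in train_data])
    y_tr = np.array([lab for _, lab in train_data])
    x_te = _pooled(ckpt, [im for im, _ in test_data])
    y_te = np.array([lab for _, lab in test_data])
    probe = LogisticRegression(max_iter=2000, random_state=seed)
    probe.fit(x_tr, y_tr)
    scores = probe.predict_proba(x_te)
    return compute_metrics(y_te, scores, seed=seed)


def _pooled(ckpt: Checkpoint, images, batch_size: int = 64) -> np.ndarray:
    arr = _pixels(images)
    chunks = []
    for lo in range(0, arr.shape[0], batch_size):
        feats = ckpt.model.token_features(arr[lo : lo + batch_size]).data
        chunks.append(feats.mean(axis=1))
    return np.concatenate(chunks, axis=0)
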