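"""Classification performance: metrics, ROC/AUC, cross-validation, embeddings.

The positive class is *impaired* throughout.  Cross-validation follows the
60/20/20 scheme: samples are split into five subject-level folds, and in
rotation ``i`` fold ``i`` is the test set, fold ``i+1 (mod 5)`` the
validation set, and the remaining three folds the training set.  All
samples of one subject share a fold, so repeated scans never leak across
the train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import roc_auc_score

from . import dlnet

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f1")


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with impaired as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise MetricsError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def classification_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, precision, sensitivity, specificity and F1, in percent.

    A ratio with a zero denominator is reported as ``None`` rather than 0.
    """
    if counts.n == 0:
        raise MetricsError("empty confusion table")

    def ratio(num, den):
        return 100.0 * num / den if den else None

    precision = ratio(counts.tp, counts.tp + counts.fp)
    sensitivity = ratio(counts.tp, counts.tp + counts.fn)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return {
        "accuracy": ratio(counts.tp + counts.tn, counts.n),
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": ratio(counts.tn, counts.tn + counts.fp),
        "f1": f1,
    }


def roc_auc(labels, scores) -> float:
    """Probability that a random impaired sample outscores a healthy one
    (ties count half); equals trapezoidal ROC integration."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise MetricsError("both classes must be present for AUC")
    return float(roc_auc_score(labels, scores))


# --------------------------------------------------------------------------
# cross-validation


@dataclass
class CvResult:
    fold_of: dict = field(default_factory=dict)  # sample id -> fold
    fold_counts: list = field(default_factory=list)
    fold_metrics: list = field(default_factory=list)
    fold_auc: list = field(default_factory=list)
    pooled_counts: ConfusionCounts | None = None
    pooled_metrics: dict = field(default_factory=dict)
    pooled_auc: float = float("nan")
    histories: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(fold=i, auc=self.fold_auc[i], **self.fold_metrics[i])
                for i in range(len(self.fold_metrics))]
        rows.append(dict(fold="pooled", auc=self.pooled_auc, **self.pooled_metrics))
        return pd.DataFrame(rows)


def subject_folds(subjects, k: int, seed: int) -> dict:
    """Assign each subject to one of ``k`` folds (shuffled round-robin).

    Returns a mapping subject -> fold index; every sample of a subject
    inherits its subject's fold.
    """
    unique = pd.unique(np.asarray(subjects))
    if len(unique) < k:
        raise MetricsError(f"need at least {k} subjects for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    return {unique[j]: i % k for i, j in enumerate(order)}


def rotation_indices(folds: np.ndarray, rotation: int, k: int):
    """Train/validation/test index arrays for one CV rotation."""
    test = np.flatnonzero(folds == rotation)
    val = np.flatnonzero(folds == (rotation + 1) % k)
    train = np.flatnonzero((folds != rotation) & (folds != (rotation + 1) % k))
    return train, val, test


def crossvalidate(
    volumes,
    labels,
    subjects,
    spec: "dlnet.NetworkSpec",
    config: "dlnet.TrainConfig",
    k: int = 5,
    seed: int = 0,
    monitor_validation: bool = False,
) -> CvResult:
    """Five-fold 60/20/20 cross-validation of the convolutional classifier.

    ``subjects`` groups samples that must share a fold.  The per-rotation
    training seed derives from ``seed`` and the rotation index so folds
    are independently reproducible.
    """
    volumes = dlnet._as_array(volumes)
    labels = np.asarray(labels).astype(int)
    subjects = np.asarray(subjects)
    if len(labels) < k:
        raise MetricsError(f"need at least {k} samples for {k} folds")
    fold_of = subject_folds(subjects, k, seed)
    folds = np.array([fold_of[s] for s in subjects])

    result = CvResult(fold_of=fold_of)
    pooled = ConfusionCounts(0, 0, 0, 0)
    all_scores, all_labels = [], []
    for rotation in range(k):
        tr, va, te = rotation_indices(folds, rotation, k)
        model = dlnet.build_network(spec)
        cfg = dlnet.TrainConfig(**{
            **config.__dict__, "seed": int(config.seed * 1000 + rotation),
        })
        history = dlnet.train(
            model, volumes[tr], labels[tr], cfg,
            val_volumes=volumes[va] if monitor_validation else None,
            val_labels=labels[va] if monitor_validation else None,
        )
        probs = dlnet.predict(model, volumes[te])
        pred = (probs >= config.decision_threshold).astype(int)
        counts = ConfusionCounts.from_labels(labels[te], pred)
        result.fold_counts.append(counts)
        result.fold_metrics.append(classification_metrics(counts))
        both = np.unique(labels[te]).size == 2
        result.fold_auc.append(roc_auc(labels[te], probs) if both else float("nan"))
        result.histories.append(history)
        pooled = pooled + counts
        all_scores.append(probs)
        all_labels.append(labels[te])
    result.pooled_counts = pooled
    result.pooled_metrics = classification_metrics(pooled)
    result.pooled_auc = roc_auc(np.concatenate(all_labels), np.concatenate(all_scores))
    return result


# --------------------------------------------------------------------------
# embeddings


def embed_2d(features, method: str = "pca", seed: int = 0) -> np.ndarray:
    """2-D embedding of network feature vectors (PCA or t-SNE)."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or len(features) < 3:
        raise MetricsError("need at least 3 feature vectors")
    if method == "pca":
        return PCA(n_components=2).fit_transform(features)
    if method == "tsne":
        perplexity = min(30.0, (len(features) - 1) / 3.0)
        return TSNE(
            n_components=2, random_state=seed, perplexity=perplexity, init="pca",
        ).fit_transform(features)
    raise MetricsError(f"unknown embedding method {method!r}")
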