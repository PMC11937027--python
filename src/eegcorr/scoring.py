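"""Channel- and clip-level anomaly scores and evaluation metrics.

A channel's score is its contribution to the invariance loss: the
squared distance between its normalized structural and semantic
embedding rows.  Channels whose own features disagree with what their
graph neighborhood predicts — weak structural/semantic correlation —
score high.  Clip scores aggregate channel scores (mean by default).

Detection quality is summarized by ranking metrics (AUC, average
precision) and by specificity at a threshold chosen as a quantile of
scores on held-out normal data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "AnomalyScores",
    "EvalReport",
    "node_scores",
    "clip_score",
    "auc",
    "average_precision",
    "specificity_at_threshold",
    "choose_threshold",
    "evaluate",
]

AGGREGATIONS = ("mean", "max")


@dataclass(frozen=True)
class AnomalyScores:
    """Scores for one clip: per-channel plus an aggregate."""

    node_scores: np.ndarray
    clip_score: float
    aggregation: str = "mean"

    def __post_init__(self):
        s = np.asarray(self.node_scores, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("node_scores must be a non-empty vector")
        if np.any(s < 0):
            raise ValueError("node scores must be nonnegative")
        object.__setattr__(self, "node_scores", s)


@dataclass(frozen=True)
class EvalReport:
    auc: float
    ap: float
    specificity: float
    threshold: float
    counts: dict

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ap": self.ap,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "counts": dict(self.counts),
        }


def node_scores(Zst_norm, Zse_norm) -> np.ndarray:
    """Per-channel anomaly score: s_i = ||z'_st,i - z'_se,i||^2.

    The scores sum to the invariance loss of the pair, so a clip's
    anomaly signal decomposes exactly over its channels.
    """
    Zst_norm = np.asarray(Zst_norm, dtype=float)
    Zse_norm = np.asarray(Zse_norm, dtype=float)
    if Zst_norm.shape != Zse_norm.shape:
        raise ValueError(f"shape mismatch {Zst_norm.shape} vs {Zse_norm.shape}")
    return ((Zst_norm - Zse_norm) ** 2).sum(axis=1)


def clip_score(scores, aggregation: str = "mean") -> float:
    """Aggregate channel scores to a clip-level score."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if aggregation == "mean":
        return float(scores.mean())
    if aggregation == "max":
        return float(scores.max())
    raise ValueError(f"unknown aggregation {aggregation!r}; expected one of {AGGREGATIONS}")


def _check_binary_both_classes(labels) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if not np.all(np.isin(classes, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present")
    return labels


def auc(scores, labels) -> float:
    """Rank-based area under the ROC curve (ties contribute 1/2)."""
    labels = _check_binary_both_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def average_precision(scores, labels) -> float:
    """Area under the precision-recall curve (step interpolation)."""
    labels = _check_binary_both_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def specificity_at_threshold(scores, labels, threshold: float):
    """True-negative rate when calling "anomalous" at score > threshold.

    Returns ``(specificity, counts)`` with the full confusion matrix.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not np.any(labels == 0):
        raise ValueError("specificity undefined without negative samples")
    pred = scores > threshold
    pos, neg = labels == 1, labels == 0
    counts = {
        "TP": int(np.sum(pred & pos)),
        "FP": int(np.sum(pred & neg)),
        "TN": int(np.sum(~pred & neg)),
        "FN": int(np.sum(~pred & pos)),
    }
    return counts["TN"] / (counts["TN"] + counts["FP"]), counts


def choose_threshold(normal_scores, q: float = 0.95) -> float:
    """Operating point: the q-th empirical quantile (linear interpolation)
    of anomaly scores on held-out normal data."""
    normal_scores = np.asarray(normal_scores, dtype=float)
    if normal_scores.size == 0:
        raise ValueError("empty normal-score sample")
    if not 0 < q <= 1:
        raise ValueError("quantile must be in (0, 1]")
    return float(np.quantile(normal_scores, q, method="linear"))


def evaluate(scores, labels, threshold: float = None, q: float = 0.95) -> EvalReport:
    """AUC, AP and specificity in one report.

    If no threshold is given, it is set to the q-quantile of the scores
    of the truly-normal items (labels == 0).
    """
    labels = _check_binary_both_classes(labels)
    scores = np.asarray(scores, dtype=float)
    if threshold is None:
        threshold = choose_threshold(scores[labels == 0], q)
    spc, counts = specificity_at_threshold(scores, labels, threshold)
    return EvalReport(
        auc=auc(scores, labels),
        ap=average_precision(scores, labels),
        specificity=float(spc),
        threshold=float(threshold),
        counts=counts,
    )
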