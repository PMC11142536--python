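"""Threshold-free and thresholded classification metrics, plus the DeLong
test for comparing two correlated ROC-AUCs.

ROC-AUC is computed by the Mann-Whitney pair-counting statistic (via
midranks), which equals the trapezoidal area under the (FPR, TPR) staircase.
The DeLong test uses per-observation structural components in the fast
midrank formulation; a naive O(n^2) kernel-matrix route is provided for
cross-checking and yields identical components.  Two-sided p-values come
from the standard normal tail and are reported as computed, never floored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreSet",
    "DeLongResult",
    "MetricsError",
    "roc_auc",
    "pr_auc",
    "thresholded_metrics",
    "delong_paired",
]


class MetricsError(ValueError):
    """Raised for invalid metric inputs."""


@dataclass
class ScoreSet:
    """Decision scores with binary labels (1 = melanoma, 0 = nevus)."""

    scores: np.ndarray
    labels: np.ndarray
    spot_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.ndim != 1 or self.labels.ndim != 1:
            raise MetricsError("scores and labels must be 1-D")
        if len(self.scores) != len(self.labels):
            raise MetricsError("scores and labels must have equal length")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise MetricsError("labels must be binary 0/1")
        if self.spot_ids is not None:
            self.spot_ids = np.asarray(self.spot_ids)
            if len(self.spot_ids) != len(self.scores):
                raise MetricsError("spot_ids length must match scores")

    def __len__(self) -> int:
        return len(self.scores)

    def require_both_classes(self) -> None:
        if self.labels.min() == self.labels.max():
            raise MetricsError("both classes must be present")


def roc_auc(s: ScoreSet) -> tuple[np.ndarray, float]:
    """ROC staircase and its area.

    The area equals the Mann-Whitney statistic
    (#{pos > neg} + 0.5 #{pos = neg}) / (n_pos * n_neg), computed via
    midranks; the returned curve is the staircase of (FPR, TPR) points over
    all distinct thresholds, whose trapezoidal area coincides with it.
    """
    s.require_both_classes()
    n_pos = int(s.labels.sum())
    n_neg = len(s) - n_pos
    ranks = rankdata(s.scores)
    auc = (ranks[s.labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s.scores, kind="mergesort")
    sorted_labels = s.labels[order]
    sorted_scores = s.scores[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1 - sorted_labels)
    # keep only the last point of each tied-score run
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    curve = np.column_stack([fpr, tpr])
    return curve, float(auc)


def pr_auc(s: ScoreSet) -> tuple[np.ndarray, float]:
    """Precision-recall staircase and its trapezoidal area.

    The curve is anchored at (recall 0, precision 1): with zero predicted
    positives precision is defined as 1 for curve stability.
    """
    s.require_both_classes()
    n_pos = int(s.labels.sum())
    order = np.argsort(-s.scores, kind="mergesort")
    sorted_labels = s.labels[order]
    sorted_scores = s.scores[order]
    tp = np.cumsum(sorted_labels)
    predicted = np.arange(1, len(s) + 1)
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    recall = np.r_[0.0, tp[distinct] / n_pos]
    precision = np.r_[1.0, tp[distinct] / predicted[distinct]]
    curve = np.column_stack([recall, precision])
    area = float(np.trapezoid(precision, recall))
    return curve, area


def thresholded_metrics(s: ScoreSet, threshold: float = 0.0) -> dict[str, float]:
    """Precision, recall and F1 at a fixed decision threshold.

    A spot is predicted melanoma when its score is >= threshold.  With no
    predicted positives precision is reported as 0 (with a logged warning);
    F1 is 0 whenever precision + recall is 0.
    """
    pred = s.scores >= threshold
    tp = int(np.sum(pred & (s.labels == 1)))
    fp = int(np.sum(pred & (s.labels == 0)))
    fn = int(np.sum(~pred & (s.labels == 1)))
    if tp + fp == 0:
        logger.warning("no predicted positives at threshold %g; precision set to 0",
                       threshold)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1}


@dataclass(frozen=True)
class DeLongResult:
    """Outcome of the paired DeLong comparison of two correlated AUCs."""

    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float


def _components_midrank(scores: np.ndarray, labels: np.ndarray):
    """Per-observation structural components via midranks (fast path)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = rankdata(pos)
    ty = rankdata(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    v01 = (tz[:m] - tx) / n        # one component per positive
    # single division keeps this bitwise equal to the kernel-matrix route
    v10 = (m - (tz[m:] - ty)) / m  # one component per negative
    return float(v01.mean()), v01, v10


def _components_naive(scores: np.ndarray, labels: np.ndarray):
    """Per-observation structural components via the O(n^2) kernel matrix."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    kernel = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v01 = kernel.mean(axis=1)
    v10 = kernel.mean(axis=0)
    return float(v01.mean()), v01, v10


def delong_paired(a: ScoreSet, b: ScoreSet, method: str = "midrank") -> DeLongResult:
    """DeLong test for two AUCs measured on the same spots.

    Both score sets must share labels and spot ids (a paired design).  The
    variance of the AUC difference is assembled from the covariance of the
    per-positive and per-negative structural components.
    """
    if method not in ("midrank", "naive"):
        raise MetricsError(f"unknown method {method!r}")
    a.require_both_classes()
    if len(a) != len(b) or not np.array_equal(a.labels, b.labels):
        raise MetricsError("score sets are not paired: labels differ")
    if a.spot_ids is not None and b.spot_ids is not None \
            and not np.array_equal(a.spot_ids, b.spot_ids):
        raise MetricsError("score sets are not paired: spot ids differ")
    components = _components_midrank if method == "midrank" else _components_naive
    auc_a, v01_a, v10_a = components(a.scores, a.labels)
    auc_b, v01_b, v10_b = components(b.scores, b.labels)
    m, n = len(v01_a), len(v10_a)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    var = (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / m \
        + (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n
    var = float(max(var, 0.0))
    diff = auc_a - auc_b
    if var == 0.0:
        if diff != 0.0:
            raise MetricsError(
                "degenerate DeLong comparison: zero variance with unequal AUCs"
            )
        z = 0.0
    else:
        z = diff / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, var_diff=var, z=float(z),
                        p_value=p)
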