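"""Self-contained evaluation metrics and rank tests.

Conventions are pinned so every number in the package is bit-stable:

* AUROC is the tie-adjusted pairwise concordance probability
  (concordant + 0.5 x tied, over all positive-negative pairs), identical
  to the trapezoidal area under the ROC over distinct thresholds.
* AUPRC uses step-wise (right-continuous) interpolation of the
  precision-recall staircase over distinct thresholds — the "average
  precision" convention, which avoids the optimistic bias of linear
  interpolation.
* The Mann-Whitney U test reports U of the *first* sample and a two-sided
  P from the normal approximation with midranks, tie-corrected variance
  and a 0.5 continuity correction.
* The chi-squared test is Pearson's statistic without continuity
  correction.
* Classification at a threshold t calls a sample positive when
  score >= t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .exceptions import UndefinedMetricError, ValidationError

__all__ = [
    "ConfusionCounts",
    "auroc",
    "auprc",
    "roc_points",
    "youden_cutpoint",
    "mann_whitney_u",
    "chi_squared",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts at one threshold."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        """Sensitivity = recall = TP / (TP + FN)."""
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fpr(self) -> float:
        """1 - specificity = FP / (FP + TN)."""
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0

    @property
    def precision(self) -> float:
        """TP / (TP + FP); defined as 1 when nothing is called positive."""
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.shape != y.shape or s.size == 0:
        raise ValidationError("scores and labels must be equal-length and non-empty")
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    if not np.isin(y, [0, 1]).all():
        raise ValidationError("labels must be binary 0/1")
    return s, y


def auroc(scores, labels) -> float:
    """Area under the ROC curve via pairwise concordance.

    Equals P(score_pos > score_neg) + 0.5 P(score_pos = score_neg) for a
    random positive-negative pair, computed in O(n log n) from midranks.
    """
    s, y = _check_scores_labels(scores, labels)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUROC undefined: both classes must be present")
    ranks = _stats.rankdata(s)  # midranks
    u1 = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve, step interpolation.

    Sum over distinct thresholds (descending) of
    (recall_i - recall_{i-1}) * precision_i.
    """
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPRC undefined: no positive samples")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    # last index of each distinct-score block = cumulative counts at that threshold
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tp = np.cumsum(y_sorted)[distinct]
    n_called = distinct + 1.0
    precision = tp / n_called
    recall = tp / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC/PR staircase over distinct thresholds (descending).

    One row per distinct score value t with the confusion counts of the
    rule ``score >= t`` plus tpr, fpr, precision, recall.
    """
    s, y = _check_scores_labels(scores, labels)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("ROC undefined: both classes must be present")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = (distinct + 1) - tp
    return pd.DataFrame(
        {
            "threshold": s_sorted[distinct],
            "tp": tp.astype(int),
            "fp": fp.astype(int),
            "fn": (n1 - tp).astype(int),
            "tn": (n0 - fp).astype(int),
            "tpr": tp / n1,
            "fpr": fp / n0,
            "precision": tp / (distinct + 1),
            "recall": tp / n1,
        }
    )


def youden_cutpoint(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties on J are broken toward the *lower* threshold.  Returns
    (threshold, sensitivity, specificity).
    """
    pts = roc_points(scores, labels)
    j = pts["tpr"] - pts["fpr"]
    # thresholds are descending; last occurrence of the max J = lowest threshold
    best = int(len(j) - 1 - np.argmax(j.to_numpy()[::-1]))
    row = pts.iloc[best]
    return float(row["threshold"]), float(row["tpr"]), float(1.0 - row["fpr"])


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U test, normal approximation, two-sided.

    Returns (U, p) where U is the U statistic of ``sample_a``.  Midranks
    handle ties; the variance carries the tie correction; a 0.5 continuity
    correction is applied toward the null mean.  When every observation is
    tied the statistic is degenerate and p = 1.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = _stats.rankdata(np.concatenate([a, b]))
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u1, 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(_stats.norm.sf(z)))
    return u1, p


def chi_squared(table) -> tuple[float, float]:
    """Pearson chi-squared test of independence, no continuity correction.

    ``table`` is an r x k array of non-negative counts with every row and
    column margin positive.  Returns (statistic, p) with
    df = (r - 1)(k - 1).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValidationError("contingency table counts must be non-negative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row <= 0).any() or (col <= 0).any():
        raise ValidationError("every margin of the contingency table must be > 0")
    expected = np.outer(row, col) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(_stats.chi2.sf(stat, df))
    return stat, p
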