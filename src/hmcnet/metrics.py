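"""Evaluation statistics: AUROC/AUPRC, Spearman/MSE, rank-sum and KS tests.

AUROC is computed as the midrank Mann-Whitney statistic divided by n1*n0 and
AUPRC by step integration of the precision-recall curve (average precision),
with tied scores processed as one group so the result does not depend on the
ordering of ties.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "auroc",
    "auprc",
    "compute_binary_metrics",
    "compute_continuous_metrics",
    "compare_methods_wilcoxon",
    "ks_two_sample",
    "MetricReport",
]


def _check_binary(labels: np.ndarray, scores: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    if labels.min() == labels.max():
        raise ValueError("AUROC/AUPRC undefined: only one class present")
    return labels, scores


def auroc(labels: Sequence[float], scores: Sequence[float]) -> float:
    """Area under the ROC curve via the midrank Mann-Whitney U statistic."""
    labels, scores = _check_binary(np.asarray(labels), np.asarray(scores))
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = stats.rankdata(scores)  # midranks
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def auprc(labels: Sequence[float], scores: Sequence[float]) -> float:
    """Average precision: sum of precision * recall increments down the
    score-sorted list, tie groups collapsed."""
    labels, scores = _check_binary(np.asarray(labels), np.asarray(scores))
    order = np.argsort(-scores, kind="mergesort")
    labels, scores = labels[order], scores[order]
    n_pos = labels.sum()
    # group boundaries where the score changes
    distinct = np.nonzero(np.diff(scores))[0]
    group_ends = np.concatenate([distinct, [len(scores) - 1]])
    tp = np.cumsum(labels)[group_ends]
    fp = np.cumsum(1 - labels)[group_ends]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def compute_binary_metrics(labels, probs) -> Tuple[float, float]:
    """(AUROC, AUPRC) for a binary task."""
    return auroc(labels, probs), auprc(labels, probs)


def compute_continuous_metrics(y, yhat) -> Tuple[float, float]:
    """(Spearman correlation, MSE) on the scale provided (log scale upstream)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or len(y) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("Spearman undefined: zero variance input")
    r = stats.spearmanr(y, yhat).statistic
    mse = float(np.mean((y - yhat) ** 2))
    return float(r), mse


def compare_methods_wilcoxon(scores_a, scores_b) -> float:
    """Two-sided Wilcoxon rank-sum p for per-tissue metric vectors.

    The comparison is deliberately unpaired (rank-sum, not signed-rank), how
    per-tissue AUROC vectors of two methods are usually contrasted.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 scores per group")
    return float(stats.ranksums(a, b).pvalue)


def ks_two_sample(x, y) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (statistic, asymptotic p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


class MetricReport(dict):
    """A metric dictionary with counts, printable as an aligned table."""

    def to_text(self) -> str:
        width = max(len(k) for k in self) if self else 0
        lines = []
        for k, v in self.items():
            if isinstance(v, float):
                lines.append(f"{k:<{width}}  {v:.6g}")
            else:
                lines.append(f"{k:<{width}}  {v}")
        return "\n".join(lines)
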