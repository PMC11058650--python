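"""Screening-performance statistics.

Virtual screens are judged on two axes: global ranking quality (ROC / AUC)
and early recognition (enrichment factor, EF).  Because validation sets are
heavily imbalanced (1 active per 50 decoys), precision-sensitive summaries —
the F1 score and the Güner-Henry (GH) score

    GH = (0.75 * precision + 0.25 * recall) * specificity

matter more than raw accuracy: a model that calls everything inactive has
high accuracy but GH = F1 = 0.  Degenerate denominators (no predicted
positives, no actives, ...) yield 0 by convention, which reproduces exactly
that collapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ConfusionCounts",
    "RankedScreen",
    "confusion",
    "rates",
    "f1",
    "gh",
    "ef",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_actives(self) -> int:
        return self.tp + self.fn

    @property
    def n_inactives(self) -> int:
        return self.fp + self.tn


@dataclass
class RankedScreen:
    """Scores and labels of a screened library, ready for ranking metrics."""

    scores: np.ndarray
    labels: np.ndarray  # 1 = active, 0 = inactive

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D arrays")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    @property
    def n_total(self) -> int:
        return len(self.labels)

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())


def confusion(predictions: Sequence[int], labels: Sequence[int]) -> ConfusionCounts:
    """Exact TP/FP/TN/FN counts from binary predictions and labels."""
    p = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("length mismatch between predictions and labels")
    if p.size == 0:
        raise ValueError("empty input")
    if not (np.isin(p, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("predictions and labels must be binary")
    return ConfusionCounts(
        tp=int(((p == 1) & (y == 1)).sum()),
        fp=int(((p == 1) & (y == 0)).sum()),
        tn=int(((p == 0) & (y == 0)).sum()),
        fn=int(((p == 0) & (y == 1)).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def rates(counts: ConfusionCounts) -> dict[str, float]:
    """Precision, recall, specificity and false-positive rate.

    Degenerate denominators yield 0 (and hence fpr = 1 - specificity keeps
    its complement relationship).
    """
    precision = _safe_div(counts.tp, counts.tp + counts.fp)
    recall = _safe_div(counts.tp, counts.tp + counts.fn)
    specificity = _safe_div(counts.tn, counts.tn + counts.fp)
    return {
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "fpr": 1.0 - specificity,
    }


def f1(counts: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    r = rates(counts)
    p, rec = r["precision"], r["recall"]
    return _safe_div(2.0 * p * rec, p + rec)


def gh(counts: ConfusionCounts) -> float:
    """Güner-Henry score (0.75*precision + 0.25*recall) * specificity."""
    r = rates(counts)
    return (0.75 * r["precision"] + 0.25 * r["recall"]) * r["specificity"]


def ef(ranked: RankedScreen, chi_percent: float = 1.0) -> float:
    """Enrichment factor EF_chi% = (n_s / N_s) * (N / n).

    N_s = ceil(chi * N / 100) molecules are taken from the top of the ranked
    list; ties at the cutoff are broken pessimistically (tied inactives are
    ranked ahead of tied actives).
    """
    if not (0.0 < chi_percent <= 100.0):
        raise ValueError("chi_percent must lie in (0, 100]")
    n_total = ranked.n_total
    n_act = ranked.n_actives
    if n_total == 0:
        raise ValueError("empty screen")
    if n_act == 0:
        raise ValueError("no actives in the screen")
    n_s_size = ceil(chi_percent * n_total / 100.0)
    # sort by score descending; within a tied score, inactives first
    order = np.lexsort((ranked.labels, -ranked.scores))
    top = ranked.labels[order][:n_s_size]
    hits = int(top.sum())
    return (hits / n_s_size) * (n_total / n_act)


def roc_auc(ranked: RankedScreen) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve points and AUC (ties contribute 1/2).

    Returns ``(fpr, tpr, auc)``.  Raises on single-class input, where the
    ROC curve is undefined.
    """
    if len(np.unique(ranked.labels)) < 2:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, _ = roc_curve(ranked.labels, ranked.scores)
    auc = float(roc_auc_score(ranked.labels, ranked.scores))
    return fpr, tpr, auc
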