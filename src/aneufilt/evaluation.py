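"""Scoring detections against ground truth: confusion counts, PR/ROC, AUC.

Detection is scored at the lesion level.  A detection is a true positive
when its centroid falls within the matched truth sphere (radius plus a
slack, default one voxel); matching is greedy one-to-one.  True negatives
are the candidate targets examined and correctly rejected — a convention
needed because lesion-level detection has no natural negative class.
Curves sweep the classification threshold over the recorded target
statistics; AUC is the trapezoidal area under the ROC, which equals the
Mann-Whitney U statistic normalized by the number of positive-negative
pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "CurvePoint",
    "match_detections",
    "metrics",
    "f1_from_precision_recall",
    "pr_roc_curves",
]


@dataclass
class ConfusionCounts:
    """Lesion-level confusion counts; TN is None when undefined."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be >= 0 or None")


@dataclass
class CurvePoint:
    threshold: float
    precision: float
    recall: float
    fpr: float


def _centroid(det) -> np.ndarray:
    if hasattr(det, "centroid"):
        return np.asarray(det.centroid, dtype=float)
    return np.asarray(det, dtype=float)


def match_detections(detections: Sequence, truth: Sequence,
                     slack: float = 1.0) -> ConfusionCounts:
    """Greedy one-to-one matching of detections to ground-truth spheres.

    A detection is a TP iff its centroid lies within ``truth.radius + slack``
    voxels of a not-yet-matched truth center (nearest such truth wins);
    unmatched detections are FP, unmatched truths FN.  Detections may be
    :class:`~aneufilt.detection.Detection` objects or bare centroids; truths
    need ``center`` and ``radius`` attributes.
    """
    matched = [False] * len(truth)
    tp = fp = 0
    for det in detections:
        c = _centroid(det)
        best_j, best_d = -1, math.inf
        for j, t in enumerate(truth):
            if matched[j]:
                continue
            d = float(np.linalg.norm(c - np.asarray(t.center, dtype=float)))
            if d <= t.radius + slack and d < best_d:
                best_j, best_d = j, d
        if best_j >= 0:
            matched[best_j] = True
            tp += 1
        else:
            fp += 1
    fn = matched.count(False)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=None)


def metrics(counts: ConfusionCounts
            ) -> tuple[float | None, float | None, float | None, float | None]:
    """(precision, recall, F1, FPR) as fractions; undefined metrics are None.

    precision = TP/(TP+FP); recall (sensitivity) = TP/(TP+FN);
    F1 = 2PR/(P+R); FPR = FP/(FP+TN).  A metric whose denominator is zero
    (or whose TN is undefined, for FPR) is reported as None, never as 0.
    """
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    f1 = None
    if p is not None and r is not None and p + r > 0:
        f1 = 2 * p * r / (p + r)
    fpr = None
    if counts.tn is not None and counts.fp + counts.tn > 0:
        fpr = counts.fp / (counts.fp + counts.tn)
    return p, r, f1, fpr


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """F1 = 2PR/(P+R); accepts fractions or percentages (same units out)."""
    if precision + recall == 0:
        raise ValueError("precision + recall must be positive")
    return 2 * precision * recall / (precision + recall)


def pr_roc_curves(scores: Iterable[tuple[float, bool]]
                  ) -> tuple[list[CurvePoint], list[CurvePoint], float]:
    """Threshold sweep over candidate scores -> (PR curve, ROC curve, AUC).

    ``scores`` pairs each candidate target's statistic with whether it is a
    true aneurysm.  A candidate is called positive when its score strictly
    exceeds the threshold; thresholds run over the unique score values (plus
    one below the minimum so recall reaches 1).  AUC is trapezoidal over
    the ROC.  Raises on single-class input.
    """
    pairs = [(float(s), bool(t)) for s, t in scores]
    if not pairs:
        raise ValueError("no scores")
    n_pos = sum(1 for _, t in pairs if t)
    n_neg = len(pairs) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative score")

    vals = np.array([s for s, _ in pairs])
    labels = np.array([t for _, t in pairs], dtype=bool)
    uniq = np.unique(vals)[::-1]
    thresholds = np.concatenate([uniq, [uniq[-1] - 1.0]])

    pr: list[CurvePoint] = []
    roc: list[CurvePoint] = []
    for th in thresholds:
        pred = vals > th
        tp = int(np.count_nonzero(pred & labels))
        fp = int(np.count_nonzero(pred & ~labels))
        fn = n_pos - tp
        tn = n_neg - fp
        prec = tp / (tp + fp) if tp + fp > 0 else 1.0
        rec = tp / (tp + fn)
        fpr = fp / (fp + tn)
        pt = CurvePoint(float(th), prec, rec, fpr)
        pr.append(pt)
        roc.append(pt)

    fprs = np.array([p.fpr for p in roc])
    tprs = np.array([p.recall for p in roc])
    order = np.argsort(fprs, kind="stable")
    auc = float(np.trapezoid(tprs[order], fprs[order]))
    return pr, roc, auc
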