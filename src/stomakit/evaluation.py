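"""From-scratch detection evaluation: IoU matching, PR curves, COCO-style AP.

The evaluation follows the COCO single-class protocol. Detections are
matched to ground truth greedily in descending confidence: each detection
claims the still-unmatched ground-truth box of highest IoU, provided that
IoU reaches the threshold (0.5 for mAP50), and is a false positive
otherwise.  Matches from all images are pooled into one global ranking,
the cumulative precision-recall curve is computed along it, and average
precision is the mean of the interpolated precision

    p_interp(r) = max { precision(r') : recall r' >= r }

evaluated at the 101 recall levels 0.00, 0.01, ..., 1.00.  With a single
class, mAP50 equals that AP at IoU 0.5.

Tie-breaking is fixed so results are reproducible everywhere: equal
confidences rank by (x_min, y_min); equal IoUs resolve to the lowest
ground-truth index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import Box, DetectionSet, GroundTruthSet, ValidationError, box_iou

__all__ = [
    "MatchLabels",
    "PRCurve",
    "APResult",
    "CountingAgreement",
    "iou",
    "match_detections",
    "pr_curve",
    "average_precision",
    "map50",
    "evaluate",
    "counting_agreement",
]

#: COCO recall grid: 101 evenly spaced levels on [0, 1].
RECALL_LEVELS = np.linspace(0.0, 1.0, 101)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; symmetric, in [0, 1]."""
    return box_iou(a, b)


@dataclass(frozen=True)
class MatchLabels:
    """Match outcome for one image's detections at one IoU threshold.

    ``confidences`` and ``tp`` are aligned and ranked by descending
    confidence (ties by x_min, then y_min); ``gt_matched`` flags each
    ground-truth box, in input order.
    """

    confidences: tuple[float, ...]
    tp: tuple[bool, ...]
    gt_matched: tuple[bool, ...]
    iou_threshold: float

    @property
    def n_gt(self) -> int:
        return len(self.gt_matched)

    @property
    def n_tp(self) -> int:
        return sum(self.tp)


@dataclass(frozen=True)
class PRCurve:
    """Cumulative precision/recall along the pooled detection ranking."""

    precision: tuple[float, ...]
    recall: tuple[float, ...]
    n_ground_truth: int


@dataclass(frozen=True)
class APResult:
    """Interpolated average precision at one IoU threshold."""

    ap: float
    iou_threshold: float
    interpolation: str = "coco-101"


@dataclass(frozen=True)
class CountingAgreement:
    """Agreement between two paired count vectors."""

    pearson_r: float
    mae: float
    n: int


def match_detections(
    detections: Sequence[Box],
    ground_truths: Sequence[Box],
    iou_threshold: float = 0.5,
) -> MatchLabels:
    """Greedily match one image's detections against its ground truth.

    Detections are visited in descending confidence; each claims the
    unmatched ground-truth box of highest IoU if that IoU is at least
    ``iou_threshold`` (a true positive), else it is a false positive.
    Each ground truth is claimed at most once.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValidationError(f"iou_threshold {iou_threshold} outside (0, 1]")
    for b in detections:
        if b.confidence is None:
            raise ValidationError("matching requires confidences on detections")
    ranked = sorted(
        detections, key=lambda b: (-b.confidence, b.x_min, b.y_min)  # type: ignore[operator]
    )
    matched = [False] * len(ground_truths)
    tp: list[bool] = []
    for det in ranked:
        best_iou = 0.0
        best_j = -1
        for j, gt in enumerate(ground_truths):
            if matched[j]:
                continue
            v = box_iou(det, gt)
            if v > best_iou:  # strict: IoU ties keep the lowest gt index
                best_iou = v
                best_j = j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            tp.append(True)
        else:
            tp.append(False)
    return MatchLabels(
        confidences=tuple(b.confidence for b in ranked),  # type: ignore[misc]
        tp=tuple(tp),
        gt_matched=tuple(matched),
        iou_threshold=iou_threshold,
    )


def pr_curve(labels: MatchLabels | Sequence[MatchLabels]) -> PRCurve:
    """Pool match labels across images and build the cumulative PR curve.

    The ranking is global: all (confidence, TP) pairs are merged and
    sorted by descending confidence (stable across the per-image lists).
    At rank k, precision = TP_k / k and recall = TP_k / n_gt.

    Raises
    ------
    ValidationError
        When there is no ground truth at all but detections exist —
        recall, hence AP, is undefined.
    """
    if isinstance(labels, MatchLabels):
        labels = [labels]
    pairs: list[tuple[float, bool]] = []
    n_gt = 0
    for lab in labels:
        n_gt += lab.n_gt
        pairs.extend(zip(lab.confidences, lab.tp))
    if n_gt == 0 and pairs:
        raise ValidationError(
            "no ground-truth boxes but detections present: AP undefined"
        )
    pairs.sort(key=lambda p: -p[0])
    precision: list[float] = []
    recall: list[float] = []
    tp_cum = 0
    for k, (_, is_tp) in enumerate(pairs, start=1):
        tp_cum += is_tp
        precision.append(tp_cum / k)
        recall.append(tp_cum / n_gt if n_gt else 0.0)
    return PRCurve(tuple(precision), tuple(recall), n_gt)


def average_precision(curve: PRCurve, iou_threshold: float = 0.5) -> APResult:
    """COCO-style 101-point interpolated AP of a PR curve.

    The precision envelope ``p_interp(r) = max precision at recall >= r``
    (0 where no point reaches recall r) is averaged over the 101 recall
    levels 0.00, 0.01, ..., 1.00.
    """
    if curve.n_ground_truth == 0:
        # no ground truth and no detections: perfect vacuous agreement
        return APResult(1.0 if not curve.precision else 0.0, iou_threshold)
    rec = np.asarray(curve.recall)
    prec = np.asarray(curve.precision)
    if rec.size == 0:
        return APResult(0.0, iou_threshold)
    # precision envelope: running maximum from the high-recall end
    order = np.argsort(rec, kind="stable")
    rec_s = rec[order]
    prec_env = np.maximum.accumulate(prec[order][::-1])[::-1]
    # for each level, first curve point with recall >= level
    idx = np.searchsorted(rec_s, RECALL_LEVELS, side="left")
    interp = np.where(idx < rec_s.size, prec_env[np.minimum(idx, rec_s.size - 1)], 0.0)
    return APResult(float(interp.mean()), iou_threshold)


def evaluate(
    detections: DetectionSet,
    ground_truths: GroundTruthSet,
    iou_threshold: float = 0.5,
) -> APResult:
    """Match, pool and score a detection set against ground truth.

    Images present in either set take part; an image with detections but
    no annotation entry contributes false positives only (never inflating
    recall).
    """
    image_ids = sorted(set(detections.image_ids) | set(ground_truths.image_ids))
    labels = [
        match_detections(
            detections.boxes(i), ground_truths.boxes(i), iou_threshold
        )
        for i in image_ids
    ]
    return average_precision(pr_curve(labels), iou_threshold)


def map50(detections: DetectionSet, ground_truths: GroundTruthSet) -> float:
    """mAP at IoU 0.5; with the single stoma class this is AP50 itself."""
    return evaluate(detections, ground_truths, iou_threshold=0.5).ap


def counting_agreement(
    predicted_counts: Sequence[float], manual_counts: Sequence[float]
) -> CountingAgreement:
    """Pearson correlation and mean absolute error of paired per-image counts.

    Needs at least three pairs of equal length.  A zero-variance vector
    makes the correlation undefined and raises.
    """
    x = np.asarray(predicted_counts, dtype=np.float64)
    y = np.asarray(manual_counts, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError(
            f"count vectors differ in length: {x.size} vs {y.size}"
        )
    if x.size < 3:
        raise ValidationError("counting agreement needs at least 3 pairs")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValidationError(
            "zero variance in a count vector: Pearson r undefined"
        )
    r = float(stats.pearsonr(x, y).statistic)
    mae = float(np.abs(x - y).mean())
    return CountingAgreement(pearson_r=r, mae=mae, n=int(x.size))
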