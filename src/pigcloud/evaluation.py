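"""Detection and segmentation metrics: precision, AP/mAP, global pixel accuracy.

Implements the standard single-class detection evaluation protocol:

* precision = TP / (TP + FP) from confusion counts;
* IoU on half-open pixel boxes or binary masks;
* greedy score-ordered matching of detections to ground truth (each ground
  truth matched at most once, best IoU above the threshold wins);
* AP as the area under the interpolated precision-recall curve, by default
  with all-point (continuous) interpolation, optionally with COCO-style
  101-point sampling;
* mAP@0.5:0.95 as the unweighted mean of the APs at the ten IoU thresholds
  0.50, 0.55, ..., 0.95;
* global pixel accuracy = trace / total of a pixel confusion matrix.

Metrics sweep all detection scores. A fixed operating confidence threshold
(the pipeline default keeps detections with score > 0.9) is a separate
filter applied before confusion counts, never before AP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "Detection",
    "GroundTruth",
    "APResult",
    "SegConfusionMatrix",
    "IOU_THRESHOLDS",
    "precision",
    "box_iou",
    "mask_iou",
    "iou",
    "match_and_ap",
    "map_over_range",
    "global_accuracy",
    "filter_by_confidence",
]

#: The ten IoU thresholds of mAP@0.5:0.95.
IOU_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))

#: Default operating confidence for accepting a detection as valid.
DEFAULT_CONF_THRESHOLD: float = 0.9


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class Detection:
    """A scored detection: box, optional binary mask, confidence, image id."""

    box: tuple[float, float, float, float]
    score: float
    image_id: str | int = 0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """A reference annotation: box, optional binary mask, image id."""

    box: tuple[float, float, float, float]
    image_id: str | int = 0
    mask: np.ndarray | None = None


@dataclass
class APResult:
    """Per-threshold AP values plus their summaries."""

    per_threshold: dict[float, float] = field(default_factory=dict)

    @property
    def map50(self) -> float:
        return self.per_threshold[0.5]

    @property
    def map5095(self) -> float:
        return float(np.mean([self.per_threshold[t] for t in IOU_THRESHOLDS]))


@dataclass
class SegConfusionMatrix:
    """An n x n pixel confusion matrix; entry (i, j) counts true-i predicted-j pixels."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.int64)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.p < 0):
            raise ValueError("confusion matrix entries must be non-negative")

    @classmethod
    def from_label_images(
        cls, truth: np.ndarray, predicted: np.ndarray, n_classes: int
    ) -> "SegConfusionMatrix":
        truth = np.asarray(truth).ravel()
        predicted = np.asarray(predicted).ravel()
        if truth.shape != predicted.shape:
            raise ValueError("label images must share a shape")
        m = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(m, (truth, predicted), 1)
        return cls(p=m)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP): the fraction of positive predictions that are correct."""
    if c.TP + c.FP == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    return c.TP / (c.TP + c.FP)


def box_iou(a: tuple[float, float, float, float], b: tuple[float, float, float, float]) -> float:
    """IoU of two half-open rectangles; 0 when disjoint."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    area_a = max(0.0, ax1 - ax0) * max(0.0, ay1 - ay0)
    area_b = max(0.0, bx1 - bx0) * max(0.0, by1 - by0)
    if area_a == 0 and area_b == 0:
        raise UndefinedMetricError("IoU undefined for two empty boxes")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    inter = max(0.0, iw) * max(0.0, ih)
    union = area_a + area_b - inter
    return inter / union


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Pixel-set IoU of two binary masks on one grid."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise UndefinedMetricError("IoU undefined for two empty masks")
    return float(np.logical_and(a, b).sum() / union)


def iou(a, b) -> float:
    """IoU dispatching on geometry kind: arrays are masks, 4-tuples are boxes."""
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        return mask_iou(a, b)
    return box_iou(tuple(a), tuple(b))


def _pair_iou(det: Detection, gt: GroundTruth, mode: str) -> float:
    if mode == "mask":
        if det.mask is None or gt.mask is None:
            raise ValueError("mask mode requires masks on detections and ground truth")
        try:
            return mask_iou(det.mask, gt.mask)
        except UndefinedMetricError:
            return 0.0
    return box_iou(det.box, gt.box)


def _match(
    dets: list[Detection],
    gts: list[GroundTruth],
    iou_threshold: float,
    mode: str,
) -> np.ndarray:
    """Greedy matching; returns a boolean TP flag per detection, score-ordered.

    Detections are visited in descending score (stable input order on ties);
    each claims the still-unmatched ground truth of its image with the
    highest IoU >= threshold.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    gt_by_image: dict = {}
    for j, g in enumerate(gts):
        gt_by_image.setdefault(g.image_id, []).append(j)
    matched = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(dets), dtype=bool)
    for rank, i in enumerate(order):
        det = dets[i]
        best_iou = -1.0
        best_j = -1
        for j in gt_by_image.get(det.image_id, []):
            if matched[j]:
                continue
            v = _pair_iou(det, gts[j], mode)
            if v >= iou_threshold and v > best_iou:
                best_iou = v
                best_j = j
        if best_j >= 0:
            matched[best_j] = True
            tp[rank] = True
    return tp


def _ap_from_flags(tp_flags: np.ndarray, n_gt: int, interpolation: str) -> float:
    """AP from score-ordered TP flags via the interpolated PR curve."""
    if n_gt == 0 or len(tp_flags) == 0:
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / n_gt
    prec = tp_cum / (tp_cum + fp_cum)
    if interpolation == "continuous":
        # All-point interpolation: area under the precision envelope.
        r = np.concatenate([[0.0], recall, [1.0]])
        p = np.concatenate([[0.0], prec, [0.0]])
        for k in range(len(p) - 2, -1, -1):
            p[k] = max(p[k], p[k + 1])
        steps = np.nonzero(r[1:] != r[:-1])[0]
        return float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))
    if interpolation == "coco101":
        # Max precision at recall >= each of 101 evenly spaced recall points.
        env = prec.copy()
        for k in range(len(env) - 2, -1, -1):
            env[k] = max(env[k], env[k + 1])
        sample = np.linspace(0.0, 1.0, 101)
        idx = np.searchsorted(recall, sample, side="left")
        vals = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
        return float(np.mean(vals))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def match_and_ap(
    dets: list[Detection],
    gts: list[GroundTruth],
    iou_threshold: float,
    mode: str = "box",
    interpolation: str = "continuous",
    conf_threshold: float | None = None,
) -> tuple[float, ConfusionCounts]:
    """Average precision at one IoU threshold, plus operating confusion counts.

    AP sweeps all detection scores. The confusion counts are taken at the
    operating point ``conf_threshold`` (all detections when None): TP/FP over
    the detections above it, FN the ground truths left unmatched by them.
    """
    tp_flags = _match(dets, gts, iou_threshold, mode)
    ap = _ap_from_flags(tp_flags, len(gts), interpolation)
    if conf_threshold is None:
        op_flags = tp_flags
        n_dets = len(dets)
    else:
        kept = filter_by_confidence(dets, conf_threshold)
        op_flags = _match(kept, gts, iou_threshold, mode)
        n_dets = len(kept)
    tp = int(op_flags.sum())
    counts = ConfusionCounts(TP=tp, FP=n_dets - tp, FN=len(gts) - tp, TN=0)
    return ap, counts


def map_over_range(
    dets: list[Detection],
    gts: list[GroundTruth],
    mode: str = "box",
    interpolation: str = "continuous",
) -> APResult:
    """AP at the ten thresholds 0.50:0.05:0.95; mAP@0.5:0.95 is their mean."""
    result = APResult()
    for t in IOU_THRESHOLDS:
        ap, _ = match_and_ap(dets, gts, float(t), mode=mode, interpolation=interpolation)
        result.per_threshold[float(t)] = ap
    return result


def global_accuracy(m: SegConfusionMatrix) -> float:
    """Fraction of pixels whose predicted class equals their true class."""
    total = int(m.p.sum())
    if total == 0:
        raise UndefinedMetricError("global accuracy undefined: no pixels")
    return float(np.trace(m.p) / total)


def filter_by_confidence(
    dets: list[Detection], threshold: float = DEFAULT_CONF_THRESHOLD
) -> list[Detection]:
    """Keep detections whose confidence exceeds the operating threshold."""
    return [d for d in dets if d.score > threshold]
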