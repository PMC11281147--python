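"""Detection-quality evaluation: IoU, greedy matching, PR curves, AP, mAP.

A predicted box counts as a true positive when its intersection-over-
union with an unmatched ground-truth box of the same class reaches the
threshold (0.5 for the headline mAP50); each ground truth can absorb at
most one detection, and detections are matched greedily in order of
descending confidence — the universal convention in detector evaluation.
Precision p = TP / (TP + FP) and recall r = TP / (number of ground-truth
boxes) are accumulated along the confidence sweep; AP is the area under
the interpolated precision envelope, and mAP50-95 averages AP over the
IoU thresholds 0.50, 0.55, ..., 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Box, Detection, ValidationError

__all__ = [
    "MatchOutcome",
    "PRCurve",
    "EvalResult",
    "iou",
    "iou_rect",
    "match_detections",
    "precision_recall_curve",
    "average_precision",
    "evaluate",
    "COCO_THRESHOLDS",
]

#: IoU thresholds 0.50:0.95:0.05 behind mAP50-95.
COCO_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class MatchOutcome:
    """TP/FP labels for detections in descending-confidence order."""

    order: tuple[int, ...]  # indices into the input detection list
    confidences: tuple[float, ...]  # sorted descending, aligned with `order`
    tp: tuple[bool, ...]  # aligned with `order`
    n_gt: int

    @property
    def tp_count(self) -> int:
        return int(sum(self.tp))

    @property
    def unmatched_gt(self) -> int:
        return self.n_gt - self.tp_count


@dataclass(frozen=True)
class PRCurve:
    """(precision, recall) points swept over detection-confidence rank."""

    precision: tuple[float, ...]
    recall: tuple[float, ...]


@dataclass(frozen=True)
class EvalResult:
    """Per-class AP at each IoU threshold plus the two headline means."""

    ap: dict  # class_id -> {threshold -> AP}
    map50: float
    map50_95: float
    curves: dict = field(default_factory=dict)  # (class_id, threshold) -> PRCurve


def iou_rect(
    a: tuple[float, float, float, float], b: tuple[float, float, float, float]
) -> float:
    """IoU of two (x0, y0, x1, y1) rectangles; 0 when disjoint."""
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(ix1 - ix0, 0.0), max(iy1 - iy0, 0.0)
    inter = iw * ih
    if inter == 0.0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two normalized boxes."""
    return iou_rect(a.corners, b.corners)


def match_detections(
    dets: list[Detection], gts: list[Box], t: float = 0.5
) -> MatchOutcome:
    """Greedy confidence-ordered matching at IoU threshold ``t``.

    Detections are processed in descending confidence (ties broken by
    input order); each is matched to the still-unmatched same-class
    ground truth with the highest IoU, and labeled TP iff that IoU >= t.
    """
    if not 0.0 < t < 1.0:
        raise ValidationError(f"IoU threshold must be in (0, 1), got {t}")
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    matched: set[int] = set()
    tp = []
    for i in order:
        det = dets[i]
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if j in matched or gt.class_id != det.box.class_id:
                continue
            v = iou(det.box, gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= t:
            matched.add(best_j)
            tp.append(True)
        else:
            tp.append(False)
    return MatchOutcome(
        order=tuple(order),
        confidences=tuple(dets[i].confidence for i in order),
        tp=tuple(tp),
        n_gt=len(gts),
    )


def precision_recall_curve(
    tp: np.ndarray | list[bool], n_gt: int
) -> PRCurve:
    """Accumulate precision/recall along a confidence-sorted TP/FP sequence.

    With no detections (or no ground truth and no detections) the curve is
    empty and AP is defined as 0.
    """
    if n_gt < 0:
        raise ValidationError("n_gt must be non-negative")
    tp_arr = np.asarray(tp, dtype=bool)
    if tp_arr.size == 0:
        return PRCurve(precision=(), recall=())
    cum_tp = np.cumsum(tp_arr)
    ranks = np.arange(1, tp_arr.size + 1)
    precision = cum_tp / ranks
    recall = cum_tp / n_gt if n_gt > 0 else np.zeros_like(precision)
    return PRCurve(precision=tuple(precision.tolist()), recall=tuple(recall.tolist()))


def average_precision(curve: PRCurve, method: str = "all_points") -> float:
    """Area under the interpolated precision envelope of a PR curve.

    ``all_points`` integrates the envelope (precision at recall r replaced
    by the maximum precision at any recall >= r) over the achieved recall
    values; ``11point`` and ``101point`` average the envelope sampled on
    the fixed recall grids used by the older benchmark conventions.
    """
    if method not in ("all_points", "11point", "101point"):
        raise ValidationError(f"unknown AP method {method!r}")
    if not curve.precision:
        return 0.0
    prec = np.asarray(curve.precision, dtype=np.float64)
    rec = np.asarray(curve.recall, dtype=np.float64)
    # precision envelope: running max from the right
    env = np.maximum.accumulate(prec[::-1])[::-1]
    if method == "all_points":
        prev_r = 0.0
        ap = 0.0
        for r, p in zip(rec, env):
            if r > prev_r:
                ap += (r - prev_r) * p
                prev_r = r
        return float(ap)
    n_points = 11 if method == "11point" else 101
    grid = np.linspace(0.0, 1.0, n_points)
    samples = np.zeros_like(grid)
    for k, g in enumerate(grid):
        mask = rec >= g - 1e-12
        samples[k] = env[mask].max() if mask.any() else 0.0
    return float(samples.mean())


def evaluate(
    dets_per_image: dict[str, list[Detection]],
    gts_per_image: dict[str, list[Box]],
    thresholds: tuple[float, ...] = COCO_THRESHOLDS,
    ap_method: str = "all_points",
    keep_curves: bool = False,
) -> EvalResult:
    """Pooled per-class evaluation over a dataset at each IoU threshold.

    mAP50 is the macro-average over classes of AP at IoU 0.5 (with a
    single class, mAP equals AP); mAP50-95 averages over classes and the
    ten thresholds.  Detections for an image id absent from the ground
    truth raise a validation error.
    """
    unknown = set(dets_per_image) - set(gts_per_image)
    if unknown:
        raise ValidationError(f"detections reference unknown image ids: {sorted(unknown)}")
    if 0.5 not in [round(t, 2) for t in thresholds]:
        raise ValidationError("threshold list must include 0.5 for mAP50")

    classes = sorted(
        {b.class_id for gts in gts_per_image.values() for b in gts}
        | {d.box.class_id for dets in dets_per_image.values() for d in dets}
    )
    ap: dict[int, dict[float, float]] = {c: {} for c in classes}
    curves: dict = {}
    for c in classes:
        n_gt = sum(1 for gts in gts_per_image.values() for b in gts if b.class_id == c)
        for t in thresholds:
            t = round(float(t), 2)
            scored: list[tuple[float, int, bool]] = []
            for img_idx, (img_id, gts) in enumerate(sorted(gts_per_image.items())):
                dets = [d for d in dets_per_image.get(img_id, []) if d.box.class_id == c]
                gts_c = [b for b in gts if b.class_id == c]
                outcome = match_detections(dets, gts_c, t)
                for conf, flag in zip(outcome.confidences, outcome.tp):
                    scored.append((conf, img_idx, flag))
            # pooled sweep: descending confidence, stable in image order
            scored.sort(key=lambda x: (-x[0], x[1]))
            curve = precision_recall_curve([f for _, _, f in scored], n_gt)
            ap[c][t] = average_precision(curve, method=ap_method)
            if keep_curves:
                curves[(c, t)] = curve

    if classes:
        map50 = float(np.mean([ap[c][0.5] for c in classes]))
        map50_95 = float(
            np.mean([ap[c][round(float(t), 2)] for c in classes for t in thresholds])
        )
    else:
        map50 = map50_95 = 0.0
    return EvalResult(ap=ap, map50=map50, map50_95=map50_95, curves=curves)
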