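"""Object-detection scoring for bounding-box predictions against ground truth.

Predictions are matched to ground truth per category with a greedy,
confidence-ordered, one-to-one assignment at an IoU threshold (the Pascal
VOC convention): each prediction, in descending confidence, claims the
unmatched same-category ground-truth box of highest IoU at or above the
threshold, else counts as a false positive.  From the matched verdicts the
module derives precision-recall curves, average precision (all-point or
11-point interpolation), mAP, operating-point precision/recall/F1 with
95% Wilson score intervals, and the mean false-positive count per image —
a workload proxy for radiologists reviewing detector output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .annot_io import BoundingBox, ImageAnnotation

__all__ = [
    "MatchResult",
    "PRCurve",
    "EvalReport",
    "box_iou",
    "match_boxes",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "operating_point_metrics",
    "wilson_interval",
    "fp_per_image",
    "evaluate",
]


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionVerdict:
    image_id: str
    category: str
    confidence: float
    is_tp: bool
    matched_gt: tuple[str, int] | None  # (image_id, gt index within image)
    iou: float


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching a prediction set against ground truth at one
    IoU threshold."""

    iou_threshold: float
    verdicts: tuple[PredictionVerdict, ...]
    n_gt: Mapping[str, int]  # per category
    n_images: int

    @property
    def tp(self) -> int:
        return sum(v.is_tp for v in self.verdicts)

    @property
    def fp(self) -> int:
        return sum(not v.is_tp for v in self.verdicts)

    @property
    def fn(self) -> int:
        return sum(self.n_gt.values()) - self.tp

    def for_category(self, category: str) -> "MatchResult":
        return MatchResult(
            iou_threshold=self.iou_threshold,
            verdicts=tuple(v for v in self.verdicts if v.category == category),
            n_gt={category: self.n_gt.get(category, 0)},
            n_images=self.n_images,
        )


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall points swept over descending confidence thresholds."""

    category: str
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    thresholds: tuple[float, ...]
    n_gt: int

    def __post_init__(self) -> None:
        if any(r2 < r1 - 1e-12 for r1, r2 in zip(self.recall, self.recall[1:])):
            raise ValueError("recall must be non-decreasing along the sweep")


@dataclass(frozen=True)
class CategoryMetrics:
    ap: float
    precision: float | None
    recall: float | None
    f1: float | None
    precision_ci: tuple[float, float] | None
    recall_ci: tuple[float, float] | None
    fp_per_image: float
    n_gt: int


@dataclass(frozen=True)
class EvalReport:
    """Per-category and aggregate detection metrics at one or more IoU
    thresholds.  ``per_threshold`` maps IoU-T -> {category -> metrics};
    ``map_per_threshold`` maps IoU-T -> mAP over included categories.
    Categories with zero ground truth are excluded from mAP and listed in
    ``excluded_categories``."""

    per_threshold: Mapping[float, Mapping[str, CategoryMetrics]]
    map_per_threshold: Mapping[float, float]
    fp_per_image_overall: Mapping[float, float]
    excluded_categories: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "mAP": {str(t): v for t, v in self.map_per_threshold.items()},
            "fp_per_image": {str(t): v for t, v in self.fp_per_image_overall.items()},
            "excluded_categories": list(self.excluded_categories),
            "per_category": {
                str(t): {
                    c: {
                        "AP": m.ap, "precision": m.precision, "recall": m.recall,
                        "f1": m.f1,
                        "precision_ci": list(m.precision_ci) if m.precision_ci else None,
                        "recall_ci": list(m.recall_ci) if m.recall_ci else None,
                        "fp_per_image": m.fp_per_image, "n_gt": m.n_gt,
                    }
                    for c, m in cats.items()
                }
                for t, cats in self.per_threshold.items()
            },
        }


# --------------------------------------------------------------------------
# IoU
# --------------------------------------------------------------------------

def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes in half-open coordinates.

    Exact for integer boxes (integer arithmetic in floats); 0 when the
    boxes are disjoint.
    """
    if a.area <= 0 or b.area <= 0:
        raise ValueError("zero-area box")
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


# --------------------------------------------------------------------------
# Matching
# --------------------------------------------------------------------------

def match_boxes(
    preds: Iterable[ImageAnnotation],
    gts: Iterable[ImageAnnotation],
    iou_t: float,
) -> MatchResult:
    """Greedy confidence-ordered one-to-one matching at IoU >= ``iou_t``.

    Matching is per image and per category; cross-category matches never
    occur.  Confidence ties are broken toward the larger IoU, then input
    order.  Every prediction must carry a confidence.
    """
    gts = list(gts)
    preds = list(preds)
    gt_by_image: dict[str, ImageAnnotation] = {g.image_id: g for g in gts}
    n_gt: dict[str, int] = {}
    for g in gts:
        for b in g.boxes:
            n_gt[b.category] = n_gt.get(b.category, 0) + 1

    # (confidence desc, input order) over all predictions of all images
    flat: list[tuple[float, int, str, int, BoundingBox]] = []
    order = 0
    for p in preds:
        for i, b in enumerate(p.boxes):
            if b.confidence is None:
                raise ValueError(
                    f"prediction without confidence on image {p.image_id!r}")
            flat.append((b.confidence, order, p.image_id, i, b))
            order += 1
    flat.sort(key=lambda t: (-t[0], t[1]))

    matched: set[tuple[str, int]] = set()  # (image_id, gt box index)
    verdicts: list[PredictionVerdict] = []
    for conf, _ord, image_id, _i, box in flat:
        gt_ann = gt_by_image.get(image_id)
        best_iou, best_key = 0.0, None
        if gt_ann is not None:
            for j, gt_box in enumerate(gt_ann.boxes):
                if gt_box.category != box.category or (image_id, j) in matched:
                    continue
                iou = box_iou(box, gt_box)
                if iou >= iou_t and iou > best_iou:
                    best_iou, best_key = iou, (image_id, j)
        if best_key is not None:
            matched.add(best_key)
            verdicts.append(PredictionVerdict(image_id, box.category, conf,
                                              True, best_key, best_iou))
        else:
            verdicts.append(PredictionVerdict(image_id, box.category, conf,
                                              False, None, best_iou))
    return MatchResult(iou_threshold=iou_t, verdicts=tuple(verdicts),
                       n_gt=n_gt, n_images=len(gts))


# --------------------------------------------------------------------------
# PR curve and AP
# --------------------------------------------------------------------------

def pr_curve(
    preds: Iterable[ImageAnnotation],
    gts: Iterable[ImageAnnotation],
    iou_t: float,
    category: str,
) -> PRCurve:
    """Precision-recall curve for one category.

    Sweeps descending over the distinct confidences of that category's
    predictions; at each threshold precision = TP/(TP+FP) and
    recall = TP / n_gt.  A category with zero ground truth cannot be
    placed on recall axes and raises."""
    match = match_boxes(preds, gts, iou_t).for_category(category)
    n_gt = match.n_gt.get(category, 0)
    if n_gt == 0:
        raise ValueError(f"category {category!r} has no ground-truth boxes")
    return _curve_from_verdicts(match.verdicts, n_gt, category)


def _curve_from_verdicts(verdicts: Sequence[PredictionVerdict], n_gt: int,
                         category: str) -> PRCurve:
    ordered = sorted(verdicts, key=lambda v: -v.confidence)
    precisions, recalls, thresholds = [], [], []
    tp = fp = 0
    i = 0
    while i < len(ordered):
        thr = ordered[i].confidence
        while i < len(ordered) and ordered[i].confidence == thr:
            if ordered[i].is_tp:
                tp += 1
            else:
                fp += 1
            i += 1
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_gt)
        thresholds.append(thr)
    return PRCurve(category=category, precision=tuple(precisions),
                   recall=tuple(recalls), thresholds=tuple(thresholds), n_gt=n_gt)


def average_precision(curve: PRCurve, method: str = "all-point") -> float:
    """Area under the precision-recall curve.

    ``"all-point"`` (default) replaces precision with its non-increasing
    envelope and sums it over recall increments; ``"11-point"`` averages
    the envelope at recalls 0, 0.1, ..., 1.0.
    """
    if len(curve.recall) == 0:
        import warnings as _w

        _w.warn("empty PR curve; AP reported as 0")
        return 0.0
    recall = np.concatenate([[0.0], np.asarray(curve.recall)])
    precision = np.concatenate([[1.0], np.asarray(curve.precision)])
    # non-increasing precision envelope from the right
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    if method == "all-point":
        return float(np.sum(np.diff(recall) * envelope[1:]))
    if method == "11-point":
        pts = []
        for r in np.linspace(0.0, 1.0, 11):
            mask = recall >= r - 1e-12
            pts.append(envelope[mask].max() if mask.any() else 0.0)
        return float(np.mean(pts))
    raise ValueError(f"unknown AP method {method!r}")


def mean_ap(per_category_ap: Mapping[str, float | None]) -> float:
    """Unweighted mean AP over included categories (``None`` = excluded)."""
    included = [v for v in per_category_ap.values() if v is not None]
    if not included:
        raise ValueError("no category with ground truth; mAP undefined")
    return float(sum(included) / len(included))


# --------------------------------------------------------------------------
# Operating-point metrics
# --------------------------------------------------------------------------

def wilson_interval(successes: int, n: int, confidence: float = 0.95,
                    ) -> tuple[float, float]:
    """95% (by default) Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - confidence, method="wilson")
    # the score interval hits 0 and 1 exactly at the boundary counts;
    # guard against floating-point residue from the closed form
    if successes == 0:
        lo = 0.0
    if successes == n:
        hi = 1.0
    return float(lo), float(hi)


def operating_point_metrics(match: MatchResult, confidence: float = 0.95) -> dict:
    """Precision, recall and F1 at a fixed operating point, with Wilson
    intervals on the two proportions.

    Precision is undefined (``None``) when there are no predictions;
    recall is undefined when there is no ground truth.
    """
    tp, fp, fn = match.tp, match.fp, match.fn
    out: dict = {"tp": tp, "fp": fp, "fn": fn}
    if tp + fp > 0:
        out["precision"] = tp / (tp + fp)
        out["precision_ci"] = wilson_interval(tp, tp + fp, confidence)
    else:
        out["precision"], out["precision_ci"] = None, None
    if tp + fn > 0:
        out["recall"] = tp / (tp + fn)
        out["recall_ci"] = wilson_interval(tp, tp + fn, confidence)
    else:
        out["recall"], out["recall_ci"] = None, None
    p, r = out["precision"], out["recall"]
    if p is None or r is None:
        out["f1"] = None
    else:
        out["f1"] = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return out


def fp_per_image(match: MatchResult) -> dict[str, float]:
    """Mean false-positive count per image, per category and overall."""
    if match.n_images <= 0:
        raise ValueError("n_images must be positive")
    counts: dict[str, int] = {}
    for v in match.verdicts:
        if not v.is_tp:
            counts[v.category] = counts.get(v.category, 0) + 1
    out = {c: n / match.n_images for c, n in sorted(counts.items())}
    out["__overall__"] = sum(counts.values()) / match.n_images
    return out


# --------------------------------------------------------------------------
# Full report
# --------------------------------------------------------------------------

def evaluate(
    preds: Sequence[ImageAnnotation],
    gts: Sequence[ImageAnnotation],
    iou_thresholds: Sequence[float] = (0.5,),
    categories: Sequence[str] | None = None,
    ap_method: str = "all-point",
    operating_confidence: float | None = None,
) -> EvalReport:
    """Score a prediction set at one or more IoU thresholds.

    ``operating_confidence``, when given, restricts the operating-point
    precision/recall/F1 to predictions at or above that confidence (the
    PR curve and AP always use all predictions).
    """
    if categories is None:
        categories = sorted({b.category for g in gts for b in g.boxes} |
                            {b.category for p in preds for b in p.boxes})
    per_threshold: dict[float, dict[str, CategoryMetrics]] = {}
    map_per_threshold: dict[float, float] = {}
    fp_overall: dict[float, float] = {}
    excluded: set[str] = set()

    op_preds = preds
    if operating_confidence is not None:
        from dataclasses import replace

        op_preds = [
            replace(p, boxes=tuple(b for b in p.boxes
                                   if b.confidence >= operating_confidence))
            for p in preds
        ]

    for t in iou_thresholds:
        match = match_boxes(preds, gts, t)
        op_match = match if op_preds is preds else match_boxes(op_preds, gts, t)
        fpi = fp_per_image(op_match)
        cats: dict[str, CategoryMetrics] = {}
        aps: dict[str, float | None] = {}
        for c in categories:
            n_gt = match.n_gt.get(c, 0)
            if n_gt == 0:
                excluded.add(c)
                aps[c] = None
                continue
            curve = _curve_from_verdicts(match.for_category(c).verdicts, n_gt, c)
            ap = average_precision(curve, ap_method)
            op = operating_point_metrics(op_match.for_category(c))
            cats[c] = CategoryMetrics(
                ap=ap, precision=op["precision"], recall=op["recall"], f1=op["f1"],
                precision_ci=op["precision_ci"], recall_ci=op["recall_ci"],
                fp_per_image=fpi.get(c, 0.0), n_gt=n_gt,
            )
            aps[c] = ap
        per_threshold[t] = cats
        map_per_threshold[t] = mean_ap(aps)
        fp_overall[t] = fpi["__overall__"]
    return EvalReport(
        per_threshold=per_threshold, map_per_threshold=map_per_threshold,
        fp_per_image_overall=fp_overall,
        excluded_categories=tuple(sorted(excluded)),
    )
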