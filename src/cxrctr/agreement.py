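"""Inter-/intra-reader agreement for bounding boxes and CTR measurements.

Reader boxes carry no confidence, so pairing between two readers uses an
optimal one-to-one assignment (Hungarian algorithm) maximizing total IoU
within each category, rather than a greedy pass.  Boxes left unpaired are
singletons with IoU = 0 — the situation where a finding is annotated by
one reader but not the other; assigned pairs with IoU = 0 are the second
situation, where both readers annotated the category but their boxes do
not overlap.

Continuous agreement between paired CTR series uses Bland-Altman limits
of agreement (mean difference ± 1.96 SD) and the intraclass correlation
coefficient computed from two-way ANOVA mean squares, defaulting to
ICC(2,1): two-way random effects, absolute agreement, single measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .annot_io import ImageAnnotation
from .detect_eval import box_iou

__all__ = [
    "BoxPair",
    "ReaderPairStats",
    "AgreementReport",
    "pair_reader_boxes",
    "reader_agreement_stats",
    "bland_altman",
    "icc",
]


@dataclass(frozen=True)
class BoxPair:
    """One category-level pairing outcome between two readers.

    ``iou`` is 0 for singletons; ``singleton_side`` is "A" or "B" when
    only one reader produced the box, else ``None``.
    """

    image_id: str
    category: str
    iou: float
    singleton_side: str | None = None


@dataclass(frozen=True)
class ReaderPairStats:
    """Aggregate agreement between two readers over a radiograph set."""

    mean_iou: Mapping[str, float]  # per category, zeros included
    mean_iou_nonzero: Mapping[str, float]  # per category, zeros excluded
    n_pairs: Mapping[str, int]
    n_zero_singleton: Mapping[str, int]  # annotated by one reader only
    n_zero_disjoint: Mapping[str, int]  # both annotated, no overlap
    n_boxes_a: int
    n_boxes_b: int
    n_images: int

    def zero_iou_count(self, category: str | None = None) -> int:
        if category is not None:
            return (self.n_zero_singleton.get(category, 0)
                    + self.n_zero_disjoint.get(category, 0))
        return (sum(self.n_zero_singleton.values())
                + sum(self.n_zero_disjoint.values()))

    def zero_iou_rate_per_image(self) -> float:
        """IoU = 0 boxes per radiograph (all categories pooled)."""
        if self.n_images == 0:
            return 0.0
        return self.zero_iou_count() / self.n_images


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman and ICC summary for one paired CTR series."""

    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    icc_value: float
    icc_form: str
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "mean_difference": self.mean_difference,
            "sd_difference": self.sd_difference,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "icc": self.icc_value,
            "icc_form": self.icc_form,
            "n_pairs": self.n_pairs,
        }


# --------------------------------------------------------------------------
# Box pairing
# --------------------------------------------------------------------------

def pair_reader_boxes(ann_a: ImageAnnotation, ann_b: ImageAnnotation,
                      ) -> list[BoxPair]:
    """Pair two readers' boxes on one radiograph, category by category.

    Within each category the one-to-one assignment maximizing total IoU is
    used; surplus boxes on either side become singletons with IoU 0.
    Symmetric in its two arguments.
    """
    if ann_a.image_id != ann_b.image_id:
        raise ValueError(
            f"image_id mismatch: {ann_a.image_id!r} vs {ann_b.image_id!r}")
    categories = sorted({b.category for b in ann_a.boxes} |
                        {b.category for b in ann_b.boxes})
    pairs: list[BoxPair] = []
    for cat in categories:
        boxes_a = [b for b in ann_a.boxes if b.category == cat]
        boxes_b = [b for b in ann_b.boxes if b.category == cat]
        iou = np.zeros((len(boxes_a), len(boxes_b)))
        for i, a in enumerate(boxes_a):
            for j, b in enumerate(boxes_b):
                iou[i, j] = box_iou(a, b)
        used_a: set[int] = set()
        used_b: set[int] = set()
        if iou.size:
            rows, cols = linear_sum_assignment(-iou)
            for i, j in zip(rows, cols):
                pairs.append(BoxPair(ann_a.image_id, cat, float(iou[i, j])))
                used_a.add(int(i))
                used_b.add(int(j))
        for i in range(len(boxes_a)):
            if i not in used_a:
                pairs.append(BoxPair(ann_a.image_id, cat, 0.0, singleton_side="A"))
        for j in range(len(boxes_b)):
            if j not in used_b:
                pairs.append(BoxPair(ann_a.image_id, cat, 0.0, singleton_side="B"))
    return pairs


def reader_agreement_stats(pairs: Iterable[BoxPair], n_images: int | None = None,
                           ) -> ReaderPairStats:
    """Aggregate per-category mean IoU and IoU = 0 counts.

    The mean IoU is reported both including IoU = 0 entries and restricted
    to overlapping pairs.  ``n_images`` defaults to the number of distinct
    image ids seen in ``pairs``.
    """
    pairs = list(pairs)
    cats = sorted({p.category for p in pairs})
    mean_iou: dict[str, float] = {}
    mean_nz: dict[str, float] = {}
    n_pairs: dict[str, int] = {}
    n_single: dict[str, int] = {}
    n_disjoint: dict[str, int] = {}
    n_a = n_b = 0
    for cat in cats:
        vals = [p.iou for p in pairs if p.category == cat]
        nz = [v for v in vals if v > 0]
        mean_iou[cat] = float(np.mean(vals)) if vals else 0.0
        mean_nz[cat] = float(np.mean(nz)) if nz else 0.0
        n_pairs[cat] = len(vals)
        n_single[cat] = sum(1 for p in pairs
                            if p.category == cat and p.singleton_side is not None)
        n_disjoint[cat] = sum(1 for p in pairs if p.category == cat
                              and p.singleton_side is None and p.iou == 0.0)
    for p in pairs:
        if p.singleton_side != "B":
            n_a += 1
        if p.singleton_side != "A":
            n_b += 1
    images = {p.image_id for p in pairs}
    return ReaderPairStats(
        mean_iou=mean_iou, mean_iou_nonzero=mean_nz, n_pairs=n_pairs,
        n_zero_singleton=n_single, n_zero_disjoint=n_disjoint,
        n_boxes_a=n_a, n_boxes_b=n_b,
        n_images=n_images if n_images is not None else len(images),
    )


# --------------------------------------------------------------------------
# Continuous agreement
# --------------------------------------------------------------------------

def bland_altman(x: Sequence[float], y: Sequence[float],
                 ) -> tuple[float, tuple[float, float]]:
    """Bland-Altman agreement between two paired series.

    Differences are ``x - y`` (convention: algorithm minus reference).
    Returns ``(mean_difference, (lower_loa, upper_loa))`` with the limits
    of agreement at mean ± 1.96 sample SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, (mean - 1.96 * sd, mean + 1.96 * sd)


def icc(x: Sequence[float], y: Sequence[float], form: str = "2,1") -> float:
    """Intraclass correlation coefficient of two paired measurement series.

    Computed from the two-way mean squares of the n-subjects x 2-raters
    layout.  Supported forms: ``"2,1"`` (two-way random effects, absolute
    agreement, single measurement — the default) and ``"3,1"`` (two-way
    mixed effects, consistency).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    data = np.column_stack([x, y])  # n subjects x k raters
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance; ICC undefined")
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_rater = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_rater
    msr = ss_subj / (n - 1)  # between-subjects
    msc = ss_rater / (k - 1)  # between-raters
    mse = ss_err / ((n - 1) * (k - 1))  # residual
    if form == "2,1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        return float((msr - mse) / denom)
    if form == "3,1":
        return float((msr - mse) / (msr + (k - 1) * mse))
    raise ValueError(f"unsupported ICC form {form!r}")


def ctr_agreement(x: Sequence[float], y: Sequence[float],
                  icc_form: str = "2,1") -> AgreementReport:
    """Bundle Bland-Altman and ICC for one paired CTR series."""
    mean, (lo, hi) = bland_altman(x, y)
    sd = (hi - mean) / 1.96
    return AgreementReport(
        mean_difference=mean, sd_difference=sd, loa_lower=lo, loa_upper=hi,
        icc_value=icc(x, y, icc_form), icc_form=f"ICC({icc_form})",
        n_pairs=len(np.asarray(x)),
    )
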