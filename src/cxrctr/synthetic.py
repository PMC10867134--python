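"""Synthetic fixtures with closed-form ground truth.

Three generator families emulate the data this toolkit measures:

* **Thorax phantoms** — lung fields modelled as ellipses with a circular
  diaphragm dome carved out of the base (so the dome apex row is an exact
  spec parameter), plus an elliptical cardiac shadow.  The phantom's true
  thoracic diameter, cardiac extent and CTR are computed from the
  noise-free raster geometry, independent of the measurement pipeline,
  making phantom batches a parameter-recovery surface for the CTR
  algorithm.  Optional boundary jitter and interior holes imitate
  imperfect segmentation-model output.

* **Detection scenarios** — per-image ground-truth boxes drawn with a
  category imbalance matching a large annotated CXR collection
  (nodule-heavy, atelectasis-poor; see :data:`TABLE1_TOTAL_BOXES`), a
  detector that hits each box with a known probability, jitters its
  localization, and adds Poisson false positives.  The implied recall and
  precision are returned in closed form.

* **Manifests** — record-level datasets for exercising the summary,
  filtering and splitting machinery, including a deterministic mode that
  reproduces the reference distribution table exactly.

A multiplicative brightness / mean-anchored contrast stress transform for
grayscale rasters rounds out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .annot_io import BoundingBox, DatasetManifest, ImageAnnotation, ManifestRecord
from .ctr import HEART, LUNG, CTRMeasurement, SegmentationMask

__all__ = [
    "CATEGORIES",
    "TABLE1_TRAIN_BOXES",
    "TABLE1_TUNE_BOXES",
    "TABLE1_TOTAL_BOXES",
    "TABLE1_IMAGE_COUNTS",
    "table1_shares",
    "PhantomSpec",
    "ScenarioSpec",
    "generate_phantom",
    "random_phantom_spec",
    "rectangular_lung_mask",
    "generate_detection_scenario",
    "generate_manifest",
    "table1_manifest",
    "perturb_image",
]


# --------------------------------------------------------------------------
# Reference abnormality distribution (14 categories)
# --------------------------------------------------------------------------

CATEGORIES: tuple[str, ...] = (
    "atelectasis", "calcification", "consolidation", "effusion", "emphysema",
    "fibrosis", "fracture", "mass", "nodule", "pleural thickening",
    "pneumatosis", "pneumothorax", "postoperative metal", "venipuncture",
)

# Per-category ground-truth bounding-box counts of the reference dataset's
# training and tuning splits; the label imbalance that scenario generation
# reproduces by default.
TABLE1_TRAIN_BOXES: Mapping[str, int] = {
    "atelectasis": 317, "calcification": 30020, "consolidation": 19103,
    "effusion": 39781, "emphysema": 21240, "fibrosis": 15043,
    "fracture": 11422, "mass": 2701, "nodule": 41438,
    "pleural thickening": 6570, "pneumatosis": 6229, "pneumothorax": 6350,
    "postoperative metal": 17845, "venipuncture": 10400,
}
TABLE1_TUNE_BOXES: Mapping[str, int] = {
    "atelectasis": 41, "calcification": 3334, "consolidation": 2163,
    "effusion": 4330, "emphysema": 2350, "fibrosis": 1644,
    "fracture": 1210, "mass": 297, "nodule": 4539,
    "pleural thickening": 823, "pneumatosis": 724, "pneumothorax": 714,
    "postoperative metal": 2084, "venipuncture": 1132,
}
TABLE1_TOTAL_BOXES: Mapping[str, int] = {
    c: TABLE1_TRAIN_BOXES[c] + TABLE1_TUNE_BOXES[c] for c in CATEGORIES
}

# Image- and patient-level tallies of the same reference splits.
TABLE1_IMAGE_COUNTS: Mapping[str, Mapping[str, int]] = {
    "training": {"images": 149425, "abnormal": 92620, "no_finding": 56805,
                 "patients": 130478},
    "tuning": {"images": 16563, "abnormal": 10284, "no_finding": 6279,
               "patients": 14490},
    "total": {"images": 165988, "abnormal": 102904, "no_finding": 63084,
              "patients": 144968},
}


def table1_shares(split: str = "total") -> dict[str, float]:
    """Per-category share (%) of total boxes in the reference table."""
    counts = {"training": TABLE1_TRAIN_BOXES, "tuning": TABLE1_TUNE_BOXES,
              "total": TABLE1_TOTAL_BOXES}[split]
    total = sum(counts.values())
    return {c: 100.0 * n / total for c, n in counts.items()}


# --------------------------------------------------------------------------
# Thorax phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Analytic thorax phantom geometry.

    Each lung is an ellipse (``lung_center_row``, per-lung center column,
    ``lung_semi_axes`` = (row, col) semi-axes) minus a circular diaphragm
    disk whose apex row (``dome_apex_rows``) and radius (``dome_radii``)
    are per-lung parameters; the dome is centered under the lung.  The
    heart is an ellipse.  ``jitter_sd`` toggles boundary-band pixels with
    probability ``min(0.5, jitter_sd/2)`` (burrs an imperfect segmenter
    would produce) and ``n_holes`` punches small interior holes; both are
    driven by ``seed``.
    """

    shape: tuple[int, int] = (512, 512)
    lung_center_row: int = 230
    lung_center_cols: tuple[int, int] = (150, 362)
    lung_semi_axes: tuple[int, int] = (170, 85)
    dome_apex_rows: tuple[int, int] = (355, 360)
    dome_radii: tuple[int, int] = (110, 110)
    heart_center: tuple[int, int] = (330, 256)
    heart_semi_axes: tuple[int, int] = (70, 68)
    jitter_sd: float = 0.0
    n_holes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.heart_semi_axes) <= 0:
            raise ValueError("heart semi-axes must be positive")
        if min(self.lung_semi_axes) <= 0:
            raise ValueError("lung semi-axes must be positive")
        rows, cols = self.shape
        for cc in self.lung_center_cols:
            if not (0 <= cc - self.lung_semi_axes[1]
                    and cc + self.lung_semi_axes[1] < cols):
                raise ValueError("lung extends outside the grid")
        if not (0 <= self.lung_center_row - self.lung_semi_axes[0]
                and self.lung_center_row + self.lung_semi_axes[0] < rows):
            raise ValueError("lung extends outside the grid")
        hr, hc = self.heart_center
        if not (0 <= hr - self.heart_semi_axes[0] and hr + self.heart_semi_axes[0] < rows
                and 0 <= hc - self.heart_semi_axes[1]
                and hc + self.heart_semi_axes[1] < cols):
            raise ValueError("heart extends outside the grid")
        lo = self.lung_center_cols[0] + self.lung_semi_axes[1]
        hi = self.lung_center_cols[1] - self.lung_semi_axes[1]
        if lo >= hi:
            raise ValueError("lungs overlap")


def generate_phantom(spec: PhantomSpec) -> tuple[SegmentationMask, CTRMeasurement]:
    """Rasterize a phantom and return it with its exact ground truth.

    The returned :class:`~cxrctr.ctr.CTRMeasurement` holds the true dome
    row (arc apex), the thoracic diameter at that row, the cardiac
    half-diameters about the heart center column, and the implied CTR —
    all read off the noise-free raster, never from the measurement
    pipeline.  Deterministic given ``spec`` (including its seed).
    """
    rows, cols = spec.shape
    rr, cc = np.ogrid[:rows, :cols]
    a_r, a_c = spec.lung_semi_axes

    lungs = []
    for side in range(2):
        c0 = spec.lung_center_cols[side]
        ellipse = ((rr - spec.lung_center_row) ** 2 / a_r**2
                   + (cc - c0) ** 2 / a_c**2) <= 1.0
        apex = spec.dome_apex_rows[side]
        radius = spec.dome_radii[side]
        dome_center_row = apex + radius
        dome = ((rr - dome_center_row) ** 2 + (cc - c0) ** 2) <= radius**2
        lungs.append(ellipse & ~dome)
    lung = lungs[0] | lungs[1]

    hr, hc = spec.heart_center
    h_r, h_c = spec.heart_semi_axes
    heart = ((rr - hr) ** 2 / h_r**2 + (cc - hc) ** 2 / h_c**2) <= 1.0
    lung &= ~heart

    truth = _phantom_truth(spec, lung, heart)

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[lung] = LUNG
    labels[heart] = HEART
    labels = _apply_noise(labels, spec)
    return SegmentationMask(labels), truth


def _phantom_truth(spec: PhantomSpec, lung: np.ndarray, heart: np.ndarray,
                   ) -> CTRMeasurement:
    apex = spec.dome_apex_rows[0]  # right lung (viewer-left) carries the tangent
    row_cols = np.nonzero(lung[apex])[0]
    if row_cols.size < 2:
        raise ValueError("dome apex row does not cross the lung fields")
    L = float(row_cols.max() - row_cols.min())
    h_cols = np.nonzero(heart.any(axis=0))[0]
    if h_cols.size == 0:
        raise ValueError("heart rasterized to zero pixels")
    midline = float(spec.heart_center[1])
    L1 = midline - float(h_cols.min())
    L2 = float(h_cols.max()) - midline
    ctr = (L1 + L2) / L
    return CTRMeasurement(
        ok=True, ctr=ctr, L=L, L1=L1, L2=L2, dome_row=apex, midline_col=midline,
        thoracic_endpoints=((apex, int(row_cols.min())), (apex, int(row_cols.max()))),
        cardiac_endpoints=((spec.heart_center[0], int(h_cols.min())),
                           (spec.heart_center[0], int(h_cols.max()))),
        cardiomegaly=ctr > 0.55,
    )


def _apply_noise(labels: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.jitter_sd <= 0 and spec.n_holes <= 0:
        return labels
    from scipy import ndimage

    rng = np.random.default_rng(spec.seed)
    out = labels.copy()
    if spec.n_holes > 0:
        for value in (LUNG, HEART):
            coords = np.argwhere(ndimage.binary_erosion(labels == value,
                                                        iterations=3))
            if coords.size == 0:
                continue
            picks = rng.choice(len(coords), size=min(spec.n_holes, len(coords)),
                               replace=False)
            for r, c in coords[picks]:
                out[max(0, r - 1):r + 2, max(0, c - 1):c + 2] = 0
    if spec.jitter_sd > 0:
        p = min(0.5, spec.jitter_sd / 2.0)
        for value in (LUNG, HEART):
            structure = labels == value
            band_out = ndimage.binary_dilation(structure) & ~structure & (out == 0)
            band_in = structure & ~ndimage.binary_erosion(structure)
            grow = band_out & (rng.random(labels.shape) < p)
            shrink = band_in & (rng.random(labels.shape) < p)
            out[grow] = value
            out[shrink & (out == value)] = 0
    return out


def random_phantom_spec(rng: np.random.Generator, target_ctr: float | None = None,
                        noisy: bool = True) -> PhantomSpec:
    """Draw a plausible random phantom; with ``target_ctr`` the heart
    width is sized so the true CTR lands near the target."""
    shape = (512, 512)
    a_r = int(rng.integers(150, 185))
    a_c = int(rng.integers(70, 95))
    gap = int(rng.integers(30, 55))
    center = 256 + int(rng.integers(-10, 11))
    c_right = center - gap // 2 - a_c
    c_left = center + gap - gap // 2 + a_c
    center_row = int(rng.integers(215, 245))
    apex_r = center_row + int(round(a_r * float(rng.uniform(0.6, 0.78))))
    apex_l = apex_r + int(rng.integers(-6, 9))
    radius = int(rng.integers(90, 130))
    # thoracic diameter implied by the geometry at the right apex row
    half = a_c * np.sqrt(max(0.0, 1 - ((apex_r - center_row) / a_r) ** 2))
    L_analytic = (c_left + half) - (c_right - half)
    ctr = float(rng.uniform(0.38, 0.62)) if target_ctr is None else target_ctr
    h_c = max(8, int(round(ctr * L_analytic / 2)))
    h_r = int(rng.integers(55, 80))
    heart_row = min(shape[0] - h_r - 1, apex_r - int(rng.integers(10, 40)))
    return PhantomSpec(
        shape=shape, lung_center_row=center_row, lung_center_cols=(c_right, c_left),
        lung_semi_axes=(a_r, a_c), dome_apex_rows=(apex_r, apex_l),
        dome_radii=(radius, radius + int(rng.integers(-10, 11))),
        heart_center=(heart_row, center), heart_semi_axes=(h_r, h_c),
        jitter_sd=0.6 if noisy else 0.0, n_holes=3 if noisy else 0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def rectangular_lung_mask(shape: tuple[int, int] = (256, 256)) -> SegmentationMask:
    """Flat-bottomed (rectangular) lung fields with a heart: every scan row
    has the same width, so diaphragm-dome detection must fail."""
    labels = np.zeros(shape, dtype=np.uint8)
    rows, cols = shape
    labels[rows // 5: 4 * rows // 5, cols // 8: 3 * cols // 8] = LUNG
    labels[rows // 5: 4 * rows // 5, 5 * cols // 8: 7 * cols // 8] = LUNG
    labels[rows // 2: 3 * rows // 4, 7 * cols // 16: 9 * cols // 16] = HEART
    return SegmentationMask(labels)


# --------------------------------------------------------------------------
# Detection scenarios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """Synthetic detector behaviour over a synthetic ground truth.

    ``category_frequencies`` defaults to the reference-table shares.
    ``hit_probability``, ``fp_rate`` (Poisson mean per image) and
    ``localization_jitter`` may be scalars or per-category mappings.
    Confidences are uniform on the stated TP/FP bands.
    """

    n_images: int = 100
    image_size: tuple[int, int] = (1024, 1024)
    boxes_per_image: float = 1.6  # Poisson mean of GT boxes per image
    category_frequencies: Mapping[str, float] | None = None
    hit_probability: float | Mapping[str, float] = 0.8
    fp_rate: float | Mapping[str, float] = 0.2
    localization_jitter: float | Mapping[str, float] = 0.0
    tp_confidence: tuple[float, float] = (0.5, 0.95)
    fp_confidence: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def frequencies(self) -> dict[str, float]:
        if self.category_frequencies is None:
            shares = table1_shares()
            return {c: shares[c] / 100.0 for c in CATEGORIES}
        total = sum(self.category_frequencies.values())
        return {c: v / total for c, v in self.category_frequencies.items()}

    def __post_init__(self) -> None:
        for name in ("hit_probability", "fp_rate", "localization_jitter"):
            v = getattr(self, name)
            vals = v.values() if isinstance(v, Mapping) else [v]
            if any(x < 0 for x in vals):
                raise ValueError(f"{name} must be non-negative")
        hp = self.hit_probability
        vals = hp.values() if isinstance(hp, Mapping) else [hp]
        if any(x > 1 for x in vals):
            raise ValueError("hit_probability must be in [0, 1]")


def _per_category(value, categories: Sequence[str]) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {c: float(value.get(c, 0.0)) for c in categories}
    return {c: float(value) for c in categories}


def generate_detection_scenario(
    spec: ScenarioSpec,
) -> tuple[list[ImageAnnotation], list[ImageAnnotation], dict]:
    """Sample ground truth and detector output with known statistics.

    Returns ``(ground_truth, predictions, expected)`` where ``expected``
    holds the closed-form recall (the hit probability), the
    ratio-of-expectations precision
    ``E[TP] / (E[TP] + E[FP])``, and the realized TP/FP/GT counts.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = spec.frequencies()
    cats = list(freqs)
    probs = np.array([freqs[c] for c in cats])
    hit = _per_category(spec.hit_probability, cats)
    fp_rate = _per_category(spec.fp_rate, cats)
    jitter = _per_category(spec.localization_jitter, cats)
    H, W = spec.image_size

    gts: list[ImageAnnotation] = []
    preds: list[ImageAnnotation] = []
    n_tp = n_fp = n_gt = 0
    for i in range(spec.n_images):
        image_id = f"synth_{i:05d}"
        n_boxes = rng.poisson(spec.boxes_per_image)
        gt_boxes: list[BoundingBox] = []
        pred_boxes: list[BoundingBox] = []
        for _ in range(n_boxes):
            cat = cats[int(rng.choice(len(cats), p=probs))]
            box = _random_box(rng, W, H, cat)
            gt_boxes.append(box)
            n_gt += 1
            if rng.random() < hit[cat]:
                pred_boxes.append(_jittered_box(rng, box, jitter[cat], W, H,
                                                float(rng.uniform(*spec.tp_confidence))))
                n_tp += 1
        for cat in cats:
            for _ in range(rng.poisson(fp_rate[cat])):
                fp_box = _random_box(rng, W, H, cat,
                                     confidence=float(rng.uniform(*spec.fp_confidence)))
                pred_boxes.append(fp_box)
                n_fp += 1
        gts.append(ImageAnnotation(image_id, W, H, tuple(gt_boxes)))
        preds.append(ImageAnnotation(image_id, W, H, tuple(pred_boxes),
                                     reader_id="synthetic-detector"))

    mean_hit = float(np.sum([freqs[c] * hit[c] for c in cats]))
    e_tp = spec.n_images * spec.boxes_per_image * mean_hit
    e_fp = spec.n_images * sum(fp_rate.values())
    expected = {
        "recall": mean_hit,
        "precision": e_tp / (e_tp + e_fp) if e_tp + e_fp > 0 else None,
        "fp_per_image": sum(fp_rate.values()),
        "n_gt": n_gt, "n_tp": n_tp, "n_fp": n_fp,
    }
    return gts, preds, expected


def _random_box(rng: np.random.Generator, W: int, H: int, category: str,
                confidence: float | None = None) -> BoundingBox:
    w = float(rng.uniform(30, min(220, W / 3)))
    h = float(rng.uniform(30, min(220, H / 3)))
    x = float(rng.uniform(0, W - w))
    y = float(rng.uniform(0, H - h))
    return BoundingBox(category, x, y, x + w, y + h, confidence)


def _jittered_box(rng: np.random.Generator, box: BoundingBox, sd: float,
                  W: int, H: int, confidence: float) -> BoundingBox:
    if sd <= 0:
        return BoundingBox(box.category, box.x_min, box.y_min, box.x_max,
                           box.y_max, confidence)
    d = rng.normal(0.0, sd, size=4)
    x0 = float(np.clip(box.x_min + d[0], 0, W - 2))
    y0 = float(np.clip(box.y_min + d[1], 0, H - 2))
    x1 = float(np.clip(box.x_max + d[2], x0 + 1, W))
    y1 = float(np.clip(box.y_max + d[3], y0 + 1, H))
    return BoundingBox(box.category, x0, y0, x1, y1, confidence)


# --------------------------------------------------------------------------
# Manifests
# --------------------------------------------------------------------------

def generate_manifest(
    n_images: int,
    no_finding_rate: float = 0.38,
    boxes_per_abnormal: float = 2.5,
    category_frequencies: Mapping[str, float] | None = None,
    seed: int = 0,
    image_size: tuple[int, int] = (2048, 2048),
) -> DatasetManifest:
    """Sample a manifest whose expected category shares follow the given
    frequencies (reference-table shares by default) and whose no-finding
    rate matches ``no_finding_rate``.  One patient per image, PA adults,
    deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    freqs = ScenarioSpec(category_frequencies=category_frequencies).frequencies()
    cats = list(freqs)
    probs = np.array([freqs[c] for c in cats])
    H, W = image_size
    records = []
    for i in range(n_images):
        image_id = f"img_{i:06d}"
        boxes: tuple[BoundingBox, ...] = ()
        if rng.random() >= no_finding_rate:
            k = max(1, rng.poisson(boxes_per_abnormal))
            boxes = tuple(
                _random_box(rng, W, H, cats[int(rng.choice(len(cats), p=probs))])
                for _ in range(k)
            )
        records.append(ManifestRecord(
            image_id=image_id, patient_id=f"pat_{i:06d}",
            age=float(np.round(rng.uniform(18, 95), 1)),
            view="PA", sex="M" if rng.random() < 0.56 else "F",
            annotation=ImageAnnotation(image_id, W, H, boxes),
        ))
    return DatasetManifest(tuple(records), CATEGORIES)


def table1_manifest(split: str = "total") -> DatasetManifest:
    """Deterministic manifest reproducing the reference distribution table.

    Per-category box counts, abnormal/no-finding image counts and the
    patient count all equal the printed table for the chosen split
    (``"training"``, ``"tuning"`` or ``"total"``); summarizing this
    manifest therefore reproduces the printed totals and shares.
    """
    counts = {"training": TABLE1_TRAIN_BOXES, "tuning": TABLE1_TUNE_BOXES,
              "total": TABLE1_TOTAL_BOXES}[split]
    level = TABLE1_IMAGE_COUNTS[split]
    n_abnormal, n_no_finding = level["abnormal"], level["no_finding"]
    n_images, n_patients = level["images"], level["patients"]

    # distribute every category's boxes round-robin over the abnormal images
    per_image_boxes: list[list[BoundingBox]] = [[] for _ in range(n_abnormal)]
    slot = 0
    box = BoundingBox("placeholder", 0, 0, 64, 64)
    for cat in CATEGORIES:
        proto = replace(box, category=cat)
        for _ in range(counts[cat]):
            per_image_boxes[slot].append(proto)
            slot = (slot + 1) % n_abnormal
    records = []
    for i in range(n_images):
        boxes = tuple(per_image_boxes[i]) if i < n_abnormal else ()
        image_id = f"t1_{i:06d}"
        records.append(ManifestRecord(
            image_id=image_id, patient_id=f"p_{i % n_patients:06d}",
            age=50.0, view="PA",
            annotation=ImageAnnotation(image_id, 2048, 2048, boxes),
        ))
    return DatasetManifest(tuple(records), CATEGORIES)


# --------------------------------------------------------------------------
# Brightness / contrast stress transform
# --------------------------------------------------------------------------

def perturb_image(image: np.ndarray, brightness: float = 1.0,
                  contrast: float = 1.0) -> np.ndarray:
    """Brightness/contrast stress transform with baseline 1.0.

    Brightness multiplies intensities; contrast rescales about the
    (brightened) image mean, ``(p - mean) * c + mean``.  Output is clipped
    to the representable range — the dtype range for integer rasters,
    ``[0, 1]`` for floating-point ones — and rounded back to integer
    dtypes.  Factors of exactly 1.0 return a bitwise-identical copy.
    """
    if brightness <= 0 or contrast < 0:
        raise ValueError("brightness and contrast factors must be positive")
    if contrast == 0:  # degenerate limit: collapse to the mean
        arr = np.asarray(image, dtype=np.float64) * brightness
        return np.full_like(image, _cast_back(arr.mean(), image.dtype))
    if brightness == 1.0 and contrast == 1.0:
        return image.copy()
    arr = np.asarray(image, dtype=np.float64) * brightness
    if contrast != 1.0:
        mean = arr.mean()
        arr = (arr - mean) * contrast + mean
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return np.clip(np.rint(arr), info.min, info.max).astype(image.dtype)
    return np.clip(arr, 0.0, 1.0).astype(image.dtype)


def _cast_back(value: float, dtype) -> np.generic:
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return dtype.type(np.clip(np.rint(value), info.min, info.max))
    return dtype.type(np.clip(value, 0.0, 1.0))
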