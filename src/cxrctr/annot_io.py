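"""Bounding-box annotation I/O and dataset-manifest bookkeeping.

Annotations live in three interchange formats common in chest-radiograph
detection work: Pascal VOC XML as written by LabelImg (1-based, inclusive
pixel coordinates), YOLO text (normalized center/size), and COCO JSON
(``bbox`` as ``[x, y, w, h]``).  Internally every box uses 0-based,
half-open pixel coordinates ``[x_min, x_max) x [y_min, y_max)`` so that
areas and intersection-over-union are exact integer arithmetic.

The manifest layer mirrors how large CXR datasets are curated: one record
per radiograph carrying patient identity, age and projection view, with
exclusion filtering (PA-only, adults-only, de-duplication), a
patient-disjoint train/tune split, and per-category summary tables.
"""

from __future__ import annotations

import csv
import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "BoundingBox",
    "ImageAnnotation",
    "ManifestRecord",
    "DatasetManifest",
    "SummaryTable",
    "ExclusionRules",
    "read_voc_annotation",
    "write_voc_annotation",
    "read_yolo_annotation",
    "write_yolo_annotation",
    "read_coco_ground_truth",
    "read_coco_results",
    "write_coco_ground_truth",
    "filter_manifest",
    "split_manifest",
    "summarize_manifest",
    "read_manifest_csv",
    "write_manifest_csv",
    "read_category_list",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundingBox:
    """One rectangular annotation in 0-based half-open pixel coordinates.

    ``confidence`` is ``None`` for ground-truth boxes and a value in
    ``[0, 1]`` for detector predictions.
    """

    category: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ValueError(f"degenerate box: x_min={self.x_min} >= x_max={self.x_max}")
        if not self.y_min < self.y_max:
            raise ValueError(f"degenerate box: y_min={self.y_min} >= y_max={self.y_max}")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass(frozen=True)
class ImageAnnotation:
    """All boxes on one image, plus image identity and size."""

    image_id: str
    width: int
    height: int
    boxes: tuple[BoundingBox, ...] = ()
    reader_id: str | None = None

    def __post_init__(self) -> None:
        if not self.image_id:
            raise ValueError("image_id must be nonempty")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image size must be positive")
        object.__setattr__(self, "boxes", tuple(self.boxes))
        for b in self.boxes:
            if b.x_min < 0 or b.y_min < 0 or b.x_max > self.width or b.y_max > self.height:
                raise ValueError(
                    f"box {b} outside image bounds {self.width}x{self.height} "
                    f"of {self.image_id!r}"
                )


@dataclass(frozen=True)
class ManifestRecord:
    """One radiograph in a dataset manifest."""

    image_id: str
    patient_id: str
    age: float | None
    view: str | None  # "PA", "AP" or "lateral"
    annotation: ImageAnnotation
    sex: str | None = None

    @property
    def no_finding(self) -> bool:
        return len(self.annotation.boxes) == 0


@dataclass(frozen=True)
class DatasetManifest:
    records: tuple[ManifestRecord, ...]
    category_list: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "category_list", tuple(self.category_list))
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i, c in Counter(ids).items() if c > 1)
            raise ValueError(f"duplicate image_id in manifest: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patient_ids(self) -> frozenset[str]:
        return frozenset(r.patient_id for r in self.records)


@dataclass(frozen=True)
class SummaryTable:
    """Per-category box counts and dataset-level tallies.

    ``category_shares`` are percentages of the total box count; rendered
    with :meth:`format` at 3 decimals, the convention of published
    distribution tables for this kind of dataset.
    """

    category_counts: Mapping[str, int]
    category_shares: Mapping[str, float]  # percent of total boxes
    total_boxes: int
    n_images: int
    n_abnormal: int
    n_no_finding: int
    n_patients: int
    abnormal_share: float  # percent of images
    no_finding_share: float
    multiplicity_counts: Mapping[str, int]  # keys "1", "2", ">=3"

    def format(self, decimals: int = 3) -> str:
        lines = [
            f"images          {self.n_images}",
            f"abnormal        {self.n_abnormal} ({self.abnormal_share:.{decimals}f}%)",
            f"no finding      {self.n_no_finding} ({self.no_finding_share:.{decimals}f}%)",
            f"patients        {self.n_patients}",
        ]
        for name, count in self.category_counts.items():
            lines.append(f"{name:<24s}{count:>8d} ({self.category_shares[name]:.{decimals}f}%)")
        lines.append(f"total boxes     {self.total_boxes}")
        lines.append(
            "images w/ 1 / 2 / >=3 abnormality categories: "
            f"{self.multiplicity_counts['1']} / {self.multiplicity_counts['2']} / "
            f"{self.multiplicity_counts['>=3']}"
        )
        return "\n".join(lines)


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be interpreted."""


# --------------------------------------------------------------------------
# Pascal VOC (LabelImg dialect)
# --------------------------------------------------------------------------

def read_voc_annotation(path: str | Path) -> ImageAnnotation:
    """Read a LabelImg-style Pascal VOC XML file.

    LabelImg writes 1-based inclusive pixel coordinates; they are shifted
    to the internal 0-based half-open convention
    (``x_min_internal = xmin_voc - 1``, ``x_max_internal = xmax_voc``).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise AnnotationParseError(f"malformed VOC XML in {path}: {exc}") from exc
    root = tree.getroot()

    size = root.find("size")
    if size is None:
        raise AnnotationParseError(f"{path}: missing <size> element")
    try:
        width = int(size.findtext("width"))
        height = int(size.findtext("height"))
    except (TypeError, ValueError) as exc:
        raise AnnotationParseError(f"{path}: unreadable <size> element") from exc

    filename = root.findtext("filename") or path.stem
    boxes: list[BoundingBox] = []
    for obj in root.iter("object"):
        name = obj.findtext("name")
        bnd = obj.find("bndbox")
        if name is None or bnd is None:
            raise AnnotationParseError(f"{path}: <object> missing <name> or <bndbox>")
        try:
            coords = {t: float(bnd.findtext(t)) for t in ("xmin", "ymin", "xmax", "ymax")}
        except (TypeError, ValueError) as exc:
            raise AnnotationParseError(f"{path}: unreadable <bndbox> in object {name!r}") from exc
        conf_text = obj.findtext("confidence")
        boxes.append(
            BoundingBox(
                category=name,
                x_min=coords["xmin"] - 1,
                y_min=coords["ymin"] - 1,
                x_max=coords["xmax"],
                y_max=coords["ymax"],
                confidence=float(conf_text) if conf_text is not None else None,
            )
        )
    return ImageAnnotation(image_id=Path(filename).stem, width=width, height=height,
                           boxes=tuple(boxes))


def write_voc_annotation(ann: ImageAnnotation, path: str | Path) -> None:
    """Write LabelImg-dialect VOC XML (1-based inclusive coordinates).

    Output is byte-stable: the same annotation always serializes to the
    same bytes.
    """
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = f"{ann.image_id}.png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(ann.width)
    etree.SubElement(size, "height").text = str(ann.height)
    etree.SubElement(size, "depth").text = "1"
    etree.SubElement(root, "segmented").text = "0"
    for b in ann.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = b.category
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        if b.confidence is not None:
            etree.SubElement(obj, "confidence").text = repr(b.confidence)
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = _coord_text(b.x_min + 1)
        etree.SubElement(bnd, "ymin").text = _coord_text(b.y_min + 1)
        etree.SubElement(bnd, "xmax").text = _coord_text(b.x_max)
        etree.SubElement(bnd, "ymax").text = _coord_text(b.y_max)
    Path(path).write_bytes(etree.tostring(root, pretty_print=True))


def _coord_text(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(v)


# --------------------------------------------------------------------------
# YOLO text
# --------------------------------------------------------------------------

def read_yolo_annotation(
    path: str | Path,
    image_width: int,
    image_height: int,
    category_list: Sequence[str],
    image_id: str | None = None,
) -> ImageAnnotation:
    """Read a YOLO txt file: ``class_idx cx cy w h [confidence]`` per line,
    with center/size normalized to ``[0, 1]``."""
    path = Path(path)
    boxes: list[BoundingBox] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise AnnotationParseError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
        idx = int(parts[0])
        if not 0 <= idx < len(category_list):
            raise AnnotationParseError(
                f"{path}:{lineno}: class index {idx} outside category list of "
                f"length {len(category_list)}"
            )
        cx, cy, w, h = (float(p) for p in parts[1:5])
        for v in (cx, cy, w, h):
            if not 0.0 <= v <= 1.0:
                raise AnnotationParseError(f"{path}:{lineno}: normalized value {v} outside [0, 1]")
        conf = float(parts[5]) if len(parts) == 6 else None
        boxes.append(
            BoundingBox(
                category=category_list[idx],
                x_min=(cx - w / 2) * image_width,
                y_min=(cy - h / 2) * image_height,
                x_max=(cx + w / 2) * image_width,
                y_max=(cy + h / 2) * image_height,
                confidence=conf,
            )
        )
    return ImageAnnotation(
        image_id=image_id or path.stem, width=image_width, height=image_height,
        boxes=tuple(boxes),
    )


def write_yolo_annotation(ann: ImageAnnotation, path: str | Path,
                          category_list: Sequence[str]) -> None:
    index = {c: i for i, c in enumerate(category_list)}
    lines = []
    for b in ann.boxes:
        if b.category not in index:
            raise ValueError(f"category {b.category!r} not in category list")
        cx = (b.x_min + b.x_max) / 2 / ann.width
        cy = (b.y_min + b.y_max) / 2 / ann.height
        w = (b.x_max - b.x_min) / ann.width
        h = (b.y_max - b.y_min) / ann.height
        fields = [str(index[b.category])] + [f"{v:.6f}" for v in (cx, cy, w, h)]
        if b.confidence is not None:
            fields.append(f"{b.confidence:.6f}")
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# --------------------------------------------------------------------------
# COCO JSON
# --------------------------------------------------------------------------

def read_coco_ground_truth(path: str | Path) -> dict[str, ImageAnnotation]:
    """Read a COCO-format ground-truth file into per-image annotations."""
    data = json.loads(Path(path).read_text())
    cats = {c["id"]: c["name"] for c in data["categories"]}
    images = {im["id"]: im for im in data["images"]}
    boxes: dict[object, list[BoundingBox]] = {im_id: [] for im_id in images}
    for a in data["annotations"]:
        x, y, w, h = a["bbox"]
        boxes[a["image_id"]].append(
            BoundingBox(category=cats[a["category_id"]],
                        x_min=x, y_min=y, x_max=x + w, y_max=y + h)
        )
    out = {}
    for im_id, im in images.items():
        name = str(im.get("file_name", im_id))
        ann = ImageAnnotation(image_id=Path(name).stem, width=im["width"],
                              height=im["height"], boxes=tuple(boxes[im_id]))
        out[ann.image_id] = ann
    return out


def read_coco_results(
    path: str | Path,
    images: Mapping[str, ImageAnnotation],
    categories: Mapping[int, str] | Sequence[str],
) -> dict[str, ImageAnnotation]:
    """Read a COCO-results prediction file (list of detections with scores).

    ``images`` supplies per-image sizes (keyed by image_id); ``categories``
    maps COCO category ids to names (a sequence is taken as ids 1..N, the
    COCO convention).
    """
    if not isinstance(categories, Mapping):
        categories = {i + 1: name for i, name in enumerate(categories)}
    dets = json.loads(Path(path).read_text())
    per_image: dict[str, list[BoundingBox]] = {im_id: [] for im_id in images}
    for d in dets:
        im_id = str(d["image_id"])
        if im_id not in per_image:
            raise AnnotationParseError(f"prediction references unknown image {im_id!r}")
        x, y, w, h = d["bbox"]
        per_image[im_id].append(
            BoundingBox(category=categories[d["category_id"]],
                        x_min=x, y_min=y, x_max=x + w, y_max=y + h,
                        confidence=float(d["score"]))
        )
    return {
        im_id: replace(images[im_id], boxes=tuple(per_image[im_id]), reader_id="model")
        for im_id in images
    }


def write_coco_ground_truth(anns: Iterable[ImageAnnotation], path: str | Path,
                            category_list: Sequence[str]) -> None:
    cat_ids = {c: i + 1 for i, c in enumerate(category_list)}
    images, annotations = [], []
    next_ann = 1
    for i, ann in enumerate(anns, start=1):
        images.append({"id": ann.image_id, "file_name": f"{ann.image_id}.png",
                       "width": ann.width, "height": ann.height})
        for b in ann.boxes:
            annotations.append({
                "id": next_ann, "image_id": ann.image_id,
                "category_id": cat_ids[b.category],
                "bbox": [b.x_min, b.y_min, b.x_max - b.x_min, b.y_max - b.y_min],
                "area": b.area, "iscrowd": 0,
            })
            next_ann += 1
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i, "name": c} for c, i in cat_ids.items()],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# --------------------------------------------------------------------------
# Manifest operations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionRules:
    """Radiograph exclusion policy: keep adult PA views, drop duplicates.

    ``duplicate_key`` selects how "duplicate" is decided: ``"image_id"``
    (default) or a callable mapping a record to a hashable key (e.g. an
    image content hash); the first occurrence of each key is kept.
    """

    allowed_views: frozenset[str] = frozenset({"PA"})
    min_age: float = 18.0
    duplicate_key: str | Callable[[ManifestRecord], object] = "image_id"


def content_hash_key(pixels: np.ndarray) -> str:
    """SHA-1 of raw pixel bytes, a content-based de-duplication key."""
    arr = np.ascontiguousarray(pixels)
    return hashlib.sha1(arr.tobytes() + str(arr.shape).encode()).hexdigest()


def filter_manifest(
    manifest: DatasetManifest,
    rules: ExclusionRules = ExclusionRules(),
) -> tuple[DatasetManifest, list[tuple[str, str]]]:
    """Apply exclusion rules; returns the filtered manifest and a log of
    ``(image_id, reason)`` pairs, one per excluded record."""
    kept: list[ManifestRecord] = []
    log: list[tuple[str, str]] = []
    seen: set[object] = set()
    keyfn = (lambda r: r.image_id) if rules.duplicate_key == "image_id" else rules.duplicate_key
    for rec in manifest.records:
        if rec.view is None or rec.age is None:
            log.append((rec.image_id, "missing metadata"))
            continue
        if rec.view not in rules.allowed_views:
            log.append((rec.image_id, f"view {rec.view}"))
            continue
        if rec.age < rules.min_age:
            log.append((rec.image_id, f"under {rules.min_age:g}"))
            continue
        key = keyfn(rec)
        if key in seen:
            log.append((rec.image_id, "duplicate"))
            continue
        seen.add(key)
        kept.append(rec)
    return DatasetManifest(tuple(kept), manifest.category_list), log


def split_manifest(
    manifest: DatasetManifest, tune_fraction: float, seed: int,
) -> tuple[DatasetManifest, DatasetManifest]:
    """Patient-disjoint train/tune split.

    All records of a patient land on the same side; the tune side receives
    ``round(tune_fraction * n_patients)`` patients, chosen by a seeded
    shuffle of the sorted patient list (deterministic given the seed).
    """
    if not 0.0 < tune_fraction < 1.0:
        raise ValueError("tune_fraction must be in (0, 1)")
    patients = sorted(manifest.patient_ids)
    n_tune = round(tune_fraction * len(patients))
    if n_tune == 0 or n_tune == len(patients):
        raise ValueError(
            f"cannot split {len(patients)} patients with tune_fraction={tune_fraction}: "
            "one side would be empty"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    tune_set = {patients[i] for i in order[:n_tune]}
    train = [r for r in manifest.records if r.patient_id not in tune_set]
    tune = [r for r in manifest.records if r.patient_id in tune_set]
    return (
        DatasetManifest(tuple(train), manifest.category_list),
        DatasetManifest(tuple(tune), manifest.category_list),
    )


def summarize_manifest(manifest: DatasetManifest) -> SummaryTable:
    """Tally per-category box counts/shares and image-level statistics.

    Shares are percentages of the total box count; image multiplicity
    counts how many *distinct* abnormality categories appear on an image
    (1, 2, or >=3).
    """
    counts = {c: 0 for c in manifest.category_list}
    n_abnormal = 0
    multiplicity = {"1": 0, "2": 0, ">=3": 0}
    for rec in manifest.records:
        if rec.no_finding:
            continue
        n_abnormal += 1
        cats = set()
        for b in rec.annotation.boxes:
            counts[b.category] = counts.get(b.category, 0) + 1
            cats.add(b.category)
        k = len(cats)
        multiplicity["1" if k == 1 else "2" if k == 2 else ">=3"] += 1
    total = sum(counts.values())
    n_images = len(manifest.records)
    shares = {c: (100.0 * n / total if total else 0.0) for c, n in counts.items()}
    return SummaryTable(
        category_counts=counts,
        category_shares=shares,
        total_boxes=total,
        n_images=n_images,
        n_abnormal=n_abnormal,
        n_no_finding=n_images - n_abnormal,
        n_patients=len(manifest.patient_ids),
        abnormal_share=100.0 * n_abnormal / n_images if n_images else 0.0,
        no_finding_share=100.0 * (n_images - n_abnormal) / n_images if n_images else 0.0,
        multiplicity_counts=multiplicity,
    )


# --------------------------------------------------------------------------
# Manifest CSV I/O
# --------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["image_id", "patient_id", "age", "sex", "view", "annotation_path"]


def write_manifest_csv(manifest: DatasetManifest, path: str | Path,
                       annotation_dir: str | Path) -> None:
    """Write the manifest as CSV plus one VOC XML file per record."""
    annotation_dir = Path(annotation_dir)
    annotation_dir.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for rec in manifest.records:
            ann_path = annotation_dir / f"{rec.image_id}.xml"
            write_voc_annotation(rec.annotation, ann_path)
            writer.writerow([
                rec.image_id, rec.patient_id,
                "" if rec.age is None else rec.age,
                rec.sex or "", rec.view or "", str(ann_path),
            ])


def read_manifest_csv(path: str | Path, category_list: Sequence[str]) -> DatasetManifest:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ann = read_voc_annotation(row["annotation_path"])
            records.append(ManifestRecord(
                image_id=row["image_id"], patient_id=row["patient_id"],
                age=float(row["age"]) if row["age"] else None,
                view=row["view"] or None, sex=row["sex"] or None,
                annotation=ann,
            ))
    return DatasetManifest(tuple(records), tuple(category_list))


def read_category_list(path: str | Path) -> tuple[str, ...]:
    """One category name per line; blank lines ignored."""
    return tuple(l.strip() for l in Path(path).read_text().splitlines() if l.strip())
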