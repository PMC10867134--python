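"""Cardiothoracic-ratio (CTR) measurement from lung/heart segmentation masks.

The CTR convention implemented here measures the thoracic diameter ``L``
along the horizontal tangent line through the dome of the right
hemidiaphragm, and the cardiac diameter as ``L1 + L2`` — the distances
from the midline to the leftmost and rightmost margins of the cardiac
shadow.  ``CTR = (L1 + L2) / L`` is dimensionless; ``CTR > 0.55``
indicates cardiomegaly under this convention.

Pipeline over a label raster (0 = background, 1 = lung, 2 = heart):

1. morphological closing per structure (removes holes and burrs);
2. keep the two largest lung components and the largest heart component;
3. extract single-pixel 8-connected structure boundaries;
4. scan horizontal lines upward from the lowest right-lung boundary pixel,
   measuring the gap between the first two left-to-right boundary
   crossings per row; the row with the maximum width jump is the tangent
   through the diaphragm dome;
5. ``L`` = distance between the extreme lung-boundary intersections on
   that row;
6. ``L1 + L2`` = distances from the midline to the extreme heart-boundary
   columns;
7. ``CTR = (L1 + L2) / L``.

All positions are pixel centers; diameters are pixel-center column
differences.  When the heart margins are not visible in the mask the CTR
cannot be calculated and the pipeline reports a machine-readable failure
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage import morphology

__all__ = [
    "SegmentationMask",
    "BoundaryMap",
    "CTRMeasurement",
    "CTRConfig",
    "CTRError",
    "clean_mask",
    "extract_boundary",
    "find_dome_row",
    "thoracic_diameter",
    "cardiac_diameter",
    "compute_ctr",
    "classify_cardiomegaly",
    "BACKGROUND",
    "LUNG",
    "HEART",
]

BACKGROUND, LUNG, HEART = 0, 1, 2

_EIGHT = np.ones((3, 3), dtype=bool)
_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class CTRError(ValueError):
    """A stage of the CTR pipeline failed; ``reason`` is machine-readable."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}{': ' + detail if detail else ''}")


@dataclass(frozen=True)
class SegmentationMask:
    """Label raster of a chest radiograph segmentation.

    ``labels`` holds 0 (background), 1 (lung) and 2 (heart).
    ``pixel_spacing`` (mm/pixel, isotropic) is carried as metadata only;
    the CTR is a ratio and never uses it.
    """

    labels: np.ndarray
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("labels must be a nonempty 2-D array")
        if arr.shape[0] < 16 or arr.shape[1] < 16:
            raise ValueError(f"mask {arr.shape} too small; need at least 16x16")
        extra = set(np.unique(arr)) - {BACKGROUND, LUNG, HEART}
        if extra:
            raise ValueError(f"unexpected label values {sorted(extra)}")
        object.__setattr__(self, "labels", arr.astype(np.uint8))

    @property
    def lung(self) -> np.ndarray:
        return self.labels == LUNG

    @property
    def heart(self) -> np.ndarray:
        return self.labels == HEART

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class BoundaryMap:
    """Single-pixel 8-connected boundary contours per structure.

    ``lung_components`` holds one boolean raster per retained lung
    component, ordered left to right by centroid column (index 0 is the
    radiographic right lung on a PA view: patient's right, viewer's left).
    """

    lung_components: tuple[np.ndarray, ...]
    heart: np.ndarray
    lung_centroid_cols: tuple[float, ...]

    @property
    def right_lung(self) -> np.ndarray:
        return self.lung_components[0]

    @property
    def all_lungs(self) -> np.ndarray:
        out = np.zeros_like(self.lung_components[0])
        for c in self.lung_components:
            out |= c
        return out


@dataclass(frozen=True)
class CTRMeasurement:
    """Full record of one CTR measurement, including intermediates.

    ``thoracic_endpoints`` and ``cardiac_endpoints`` are ``(row, col)``
    pixel coordinates of the measured extremes.  ``ok`` is False when a
    pipeline stage failed, with the machine-readable cause in
    ``failure_reason``.
    """

    ok: bool
    ctr: float | None = None
    L: float | None = None
    L1: float | None = None
    L2: float | None = None
    dome_row: int | None = None
    midline_col: float | None = None
    thoracic_endpoints: tuple[tuple[int, int], tuple[int, int]] | None = None
    cardiac_endpoints: tuple[tuple[int, int], tuple[int, int]] | None = None
    cardiomegaly: bool | None = None
    failure_reason: str | None = None
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "ok", "ctr", "L", "L1", "L2", "dome_row", "midline_col",
            "cardiomegaly", "failure_reason")}
        d["thoracic_endpoints"] = (
            [list(p) for p in self.thoracic_endpoints] if self.thoracic_endpoints else None)
        d["cardiac_endpoints"] = (
            [list(p) for p in self.cardiac_endpoints] if self.cardiac_endpoints else None)
        d["warnings"] = list(self.warnings)
        return d


@dataclass(frozen=True)
class CTRConfig:
    """Tunable parameters of the CTR pipeline.

    ``closing_radius`` is the disk radius (pixels) of the per-structure
    morphological closing at a 512-px mask; it is rescaled proportionally
    to the actual mask size.  ``scan_step`` is the row stride of the
    upward diaphragm scan.  ``right_lung`` selects which lung carries the
    diaphragm dome: on a PA radiograph the patient's right lung appears on
    the viewer's left (smaller columns); set ``"viewer-right"`` to
    override.  ``cardiomegaly_threshold`` is the CTR cut-off (strict
    inequality).
    """

    closing_radius: float = 3.0
    reference_size: int = 512
    scan_step: int = 1
    scan_fraction: float = 0.5
    right_lung: str = "viewer-left"
    cardiomegaly_threshold: float = 0.55


# --------------------------------------------------------------------------
# Steps 1-2: cleaning
# --------------------------------------------------------------------------

def clean_mask(mask: SegmentationMask, closing_radius: float = 3.0,
               reference_size: int = 512) -> SegmentationMask:
    """Morphological smoothing per structure (closing to fill holes, then
    opening to shave burrs), keeping the two largest 8-connected lung
    components and the single largest heart component.

    The disk radius is ``closing_radius`` at a ``reference_size``-px mask
    and scales proportionally with ``max(mask.shape)``.
    """
    scale = max(mask.shape) / reference_size
    radius = max(1, int(round(closing_radius * scale)))
    selem = morphology.disk(radius)

    lung = _smooth(mask.lung, selem)
    heart = _smooth(mask.heart, selem)
    heart &= ~lung  # smoothing may spill labels onto each other; lung wins ties

    lung = _keep_largest(lung, n=2, what="lung")
    if not heart.any():
        raise CTRError("heart absent", "no heart pixels in mask")
    heart = _keep_largest(heart, n=1, what="heart")

    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[lung] = LUNG
    labels[heart] = HEART
    return SegmentationMask(labels, mask.pixel_spacing)


def _smooth(binary: np.ndarray, selem: np.ndarray) -> np.ndarray:
    closed = ndimage.binary_closing(binary, structure=selem, border_value=0)
    return ndimage.binary_opening(closed, structure=selem, border_value=0)


def _keep_largest(binary: np.ndarray, n: int, what: str) -> np.ndarray:
    lab, n_comp = ndimage.label(binary, structure=_EIGHT)
    if what == "lung" and n_comp < 2:
        raise CTRError("lungs not separable",
                       f"found {n_comp} lung component(s), need 2")
    if n_comp == 0:
        raise CTRError(f"{what} absent")
    sizes = ndimage.sum_labels(binary, lab, index=np.arange(1, n_comp + 1))
    keep = np.argsort(sizes)[::-1][:n] + 1
    return np.isin(lab, keep)


# --------------------------------------------------------------------------
# Step 3: boundary extraction
# --------------------------------------------------------------------------

def extract_boundary(mask: SegmentationMask) -> BoundaryMap:
    """Single-pixel boundaries of each lung component and the heart.

    The boundary of a binary structure is the structure minus its
    4-connected erosion: every boundary pixel belongs to the structure and
    touches the outside through a 4-neighbor, and the resulting contour is
    8-connected and one pixel wide.
    """
    lung_lab, n_lung = ndimage.label(mask.lung, structure=_EIGHT)
    if n_lung < 2:
        raise CTRError("lungs not separable", f"found {n_lung} lung component(s)")

    comps: list[np.ndarray] = []
    cols: list[float] = []
    for i in range(1, n_lung + 1):
        comp = lung_lab == i
        comps.append(_contour(comp, "lung"))
        cols.append(float(np.mean(np.nonzero(comp)[1])))
    order = np.argsort(cols)
    heart = _contour(mask.heart, "heart")
    return BoundaryMap(
        lung_components=tuple(comps[i] for i in order),
        heart=heart,
        lung_centroid_cols=tuple(cols[i] for i in order),
    )


def _contour(binary: np.ndarray, what: str) -> np.ndarray:
    if not binary.any():
        raise CTRError(f"{what} absent")
    rows, cols = np.nonzero(binary)
    if binary.sum() < 4 or np.ptp(rows) < 1 or np.ptp(cols) < 1:
        raise CTRError("degenerate structure",
                       f"{what} too thin for a contour ({int(binary.sum())} px)")
    interior = ndimage.binary_erosion(binary, structure=_FOUR, border_value=0)
    return binary & ~interior


# --------------------------------------------------------------------------
# Step 4: diaphragm dome
# --------------------------------------------------------------------------

def find_dome_row(right_lung_boundary: np.ndarray, scan_step: int = 1,
                  scan_fraction: float = 0.5) -> tuple[int, dict[int, float]]:
    """Locate the tangent row through the right hemidiaphragm dome.

    Starting at the lowest boundary row and moving upward in steps of
    ``scan_step``, each row's first two left-to-right boundary crossings
    (maximal runs of consecutive boundary columns) bound a width.  Below
    the dome these crossings are the lateral chest wall and the diaphragm
    arc; at the first row clear of the arc the width jumps to the full
    lung width.  The returned row maximizes the signed width *increase*
    between consecutive scanned rows (tie-break: most inferior): the
    tangent through the dome is the line at which the width expands to
    the chest width, so only increases identify it — near the
    costophrenic recesses the first-two-crossings width can also collapse
    abruptly, and those decreases are not dome evidence.  The returned
    row is the lower row of the maximizing pair: the last line that still
    meets the diaphragm, i.e. the one grazing the dome.  Rows
    with fewer than two crossings are skipped; three consecutive skipped
    rows above the last measurable one end the scan.

    The scan covers the inferior ``scan_fraction`` of the contour's row
    extent: the diaphragm is inferior by anatomy, and the superior lung
    apex — where the contour also narrows row by row — must not compete
    with it.

    Returns ``(dome_row, width_trace)`` where ``width_trace`` maps each
    measured row to its width.
    """
    if scan_step < 1:
        raise ValueError("scan_step must be >= 1")
    if not 0.0 < scan_fraction <= 1.0:
        raise ValueError("scan_fraction must be in (0, 1]")
    rows_px, cols_px = np.nonzero(right_lung_boundary)
    if rows_px.size == 0:
        raise CTRError("dome undetectable", "empty contour")
    by_row: dict[int, np.ndarray] = {}
    for r in np.unique(rows_px):
        by_row[int(r)] = np.sort(cols_px[rows_px == r])

    bottom = int(rows_px.max())
    top = int(rows_px.min())
    stop = bottom - int(round(scan_fraction * (bottom - top)))

    trace: dict[int, float] = {}
    skipped = 0
    last_valid = None
    for row in range(bottom, stop - 1, -scan_step):
        crossings = _crossing_positions(by_row.get(row, np.empty(0, dtype=int)))
        if len(crossings) < 2:
            if last_valid is not None:
                skipped += 1
                if skipped >= 3:
                    break
            continue
        skipped = 0
        trace[row] = float(crossings[1] - crossings[0])
        last_valid = row

    if len(trace) == 0:
        raise CTRError("dome undetectable", "no scanned row has two boundary crossings")
    rows_sorted = sorted(trace, reverse=True)  # inferior -> superior
    best_row, best_diff = None, 0.0
    for lower, upper in zip(rows_sorted, rows_sorted[1:]):
        diff = trace[upper] - trace[lower]
        # the tangent grazes the dome: it is the lower row of the pair, the
        # last line still meeting the diaphragm before the width expands;
        # strict > keeps the most inferior row on ties
        if diff > best_diff:
            best_diff, best_row = diff, lower
    if best_row is None:
        raise CTRError("flat diaphragm",
                       "width trace never increases; dome ambiguous")
    return best_row, trace


def _crossing_positions(cols: np.ndarray) -> list[int]:
    """Collapse a sorted column list into maximal consecutive runs; each
    run is one boundary crossing, positioned at its leftmost column."""
    if cols.size == 0:
        return []
    starts = [int(cols[0])]
    for prev, cur in zip(cols[:-1], cols[1:]):
        if cur > prev + 1:
            starts.append(int(cur))
    return starts


# --------------------------------------------------------------------------
# Steps 5-6: diameters
# --------------------------------------------------------------------------

def thoracic_diameter(lung_boundary: np.ndarray, dome_row: int,
                      ) -> tuple[float, tuple[tuple[int, int], tuple[int, int]]]:
    """Thoracic diameter ``L``: pixel-center distance between the extreme
    intersections of the dome tangent row with both lung boundaries."""
    cols = np.nonzero(lung_boundary[dome_row])[0]
    if cols.size < 2:
        raise CTRError("tangent outside lung extent",
                       f"row {dome_row} crosses the lung boundary {cols.size} time(s)")
    left, right = int(cols.min()), int(cols.max())
    return float(right - left), ((dome_row, left), (dome_row, right))


def cardiac_diameter(heart_boundary: np.ndarray, midline_col: float,
                     ) -> tuple[float, float, tuple[tuple[int, int], tuple[int, int]], tuple[str, ...]]:
    """Cardiac half-diameters ``L1`` (midline to leftmost heart margin)
    and ``L2`` (rightmost margin to midline).

    When the midline lies strictly between the extremes, ``L1 + L2``
    equals the heart's horizontal pixel extent and is independent of the
    exact midline column; otherwise a quality warning is attached.
    """
    rows, cols = np.nonzero(heart_boundary)
    if rows.size == 0:
        raise CTRError("heart absent", "empty heart contour")
    left = int(cols.min())
    right = int(cols.max())
    L1 = abs(midline_col - left)
    L2 = abs(right - midline_col)
    warnings: tuple[str, ...] = ()
    if not (left < midline_col < right):
        warnings = ("midline outside cardiac extent; L1+L2 exceeds the heart width",)
    left_row = int(rows[cols == left][0])
    right_row = int(rows[cols == right][0])
    return float(L1), float(L2), ((left_row, left), (right_row, right)), warnings


# --------------------------------------------------------------------------
# Step 7: orchestration
# --------------------------------------------------------------------------

def compute_ctr(mask: SegmentationMask, config: CTRConfig = CTRConfig()) -> CTRMeasurement:
    """Run the full pipeline and return a :class:`CTRMeasurement`.

    Deterministic: identical mask and config give an identical result.
    Stage failures do not raise; they yield ``ok=False`` with the failure
    reason, mirroring radiographs on which the CTR cannot be calculated.
    """
    try:
        cleaned = clean_mask(mask, config.closing_radius, config.reference_size)
        boundaries = extract_boundary(cleaned)

        right = (boundaries.lung_components[0] if config.right_lung == "viewer-left"
                 else boundaries.lung_components[-1])
        dome_row, _trace = find_dome_row(right, config.scan_step, config.scan_fraction)
        L, thoracic_pts = thoracic_diameter(boundaries.all_lungs, dome_row)
        midline = float(np.mean(boundaries.lung_centroid_cols))
        L1, L2, cardiac_pts, warnings = cardiac_diameter(boundaries.heart, midline)
    except CTRError as exc:
        return CTRMeasurement(ok=False, failure_reason=exc.reason)

    ctr = (L1 + L2) / L
    if ctr > 1.0:
        warnings = warnings + ("ctr exceeds 1.0; check the mask",)
    return CTRMeasurement(
        ok=True, ctr=ctr, L=L, L1=L1, L2=L2, dome_row=dome_row,
        midline_col=midline, thoracic_endpoints=thoracic_pts,
        cardiac_endpoints=cardiac_pts,
        cardiomegaly=classify_cardiomegaly(ctr, config.cardiomegaly_threshold),
        warnings=warnings,
    )


def classify_cardiomegaly(ctr: float, threshold: float = 0.55) -> bool:
    """Cardiomegaly iff ``ctr > threshold`` (strict)."""
    if ctr <= 0:
        raise ValueError("ctr must be positive")
    return ctr > threshold


# --------------------------------------------------------------------------
# Mask raster I/O
# --------------------------------------------------------------------------

def read_mask_png(path) -> SegmentationMask:
    """Read a single-channel PNG label raster (values 0/1/2)."""
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("I"))
    return SegmentationMask(arr)


def write_mask_png(mask: SegmentationMask, path) -> None:
    from PIL import Image

    Image.fromarray(mask.labels, mode="L").save(path)


def render_overlay(mask: SegmentationMask, result: CTRMeasurement, path) -> None:
    """Write an overlay PNG drawing the tangent line, midline and the
    thoracic/cardiac diameter segments over the mask."""
    from PIL import Image, ImageDraw

    img = Image.fromarray((mask.labels * 100).astype(np.uint8), mode="L").convert("RGB")
    if result.ok:
        draw = ImageDraw.Draw(img)
        w = mask.shape[1]
        draw.line([(0, result.dome_row), (w - 1, result.dome_row)], fill=(255, 200, 0))
        draw.line([(result.midline_col, 0), (result.midline_col, mask.shape[0] - 1)],
                  fill=(0, 200, 255))
        (r1, c1), (r2, c2) = result.thoracic_endpoints
        draw.line([(c1, r1), (c2, r2)], fill=(255, 0, 0), width=2)
        (r1, c1), (r2, c2) = result.cardiac_endpoints
        draw.line([(c1, r1), (c2, r2)], fill=(0, 255, 0), width=2)
    img.save(path)
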