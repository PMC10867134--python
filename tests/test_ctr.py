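"""Geometric CTR pipeline: cleaning, boundaries, dome detection, diameters."""

import numpy as np
import pytest
from scipy import ndimage

from cxrctr.ctr import (
    HEART,
    LUNG,
    CTRConfig,
    CTRError,
    SegmentationMask,
    cardiac_diameter,
    classify_cardiomegaly,
    clean_mask,
    compute_ctr,
    extract_boundary,
    find_dome_row,
    thoracic_diameter,
)
from cxrctr.synthetic import (
    PhantomSpec,
    generate_phantom,
    random_phantom_spec,
    rectangular_lung_mask,
)


def two_lung_mask(with_heart=True, size=64):
    """Two rectangular lungs spanning cols [10,40) and [60 -> scaled]."""
    labels = np.zeros((size, size), dtype=np.uint8)
    labels[10:50, 8:24] = LUNG
    labels[10:50, 40:56] = LUNG
    if with_heart:
        labels[30:45, 26:38] = HEART
    return SegmentationMask(labels)


class TestCleanMask:
    def test_interior_hole_filled(self):
        mask = two_lung_mask()
        labels = mask.labels.copy()
        labels[20:23, 12:15] = 0  # 3-px hole inside the left rectangle
        cleaned = clean_mask(SegmentationMask(labels), closing_radius=2,
                             reference_size=64)
        assert cleaned.labels[21, 13] == LUNG

    def test_two_largest_lung_components_kept(self):
        labels = two_lung_mask().labels.copy()
        labels[2:4, 2:7] = LUNG  # 10-px stray component
        cleaned = clean_mask(SegmentationMask(labels), closing_radius=1,
                             reference_size=512)
        assert cleaned.labels[2, 3] == 0
        _, n = ndimage.label(cleaned.lung, structure=np.ones((3, 3)))
        assert n == 2

    def test_heart_absent_raises(self):
        with pytest.raises(CTRError, match="heart absent"):
            clean_mask(two_lung_mask(with_heart=False))

    def test_single_lung_not_separable(self):
        labels = np.zeros((64, 64), dtype=np.uint8)
        labels[10:50, 10:50] = LUNG
        labels[52:60, 20:40] = HEART
        with pytest.raises(CTRError, match="lungs not separable"):
            clean_mask(SegmentationMask(labels))


class TestExtractBoundary:
    def test_square_perimeter_ring(self):
        # a 10x10 solid component has a 36-pixel one-pixel-wide ring
        labels = np.zeros((64, 64), dtype=np.uint8)
        labels[5:15, 5:15] = LUNG
        labels[5:15, 40:50] = LUNG
        labels[40:50, 20:30] = HEART
        b = extract_boundary(SegmentationMask(labels))
        assert int(b.lung_components[0].sum()) == 36
        assert int(b.heart.sum()) == 36

    def test_boundary_pixels_touch_background(self):
        mask, _ = generate_phantom(PhantomSpec())
        cleaned = clean_mask(mask)
        b = extract_boundary(cleaned)
        for contour, structure in ((b.heart, cleaned.labels == HEART),):
            rows, cols = np.nonzero(contour)
            eroded = ndimage.binary_erosion(
                structure, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
            assert not eroded[rows, cols].any()

    def test_single_row_structure_degenerate(self):
        labels = np.zeros((64, 64), dtype=np.uint8)
        labels[10:40, 5:20] = LUNG
        labels[10:40, 40:55] = LUNG
        labels[50, 25:35] = HEART  # one row thick
        with pytest.raises(CTRError, match="degenerate"):
            extract_boundary(SegmentationMask(labels))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_idempotence_on_random_blobs(self, seed):
        # filling the contour's interior and re-extracting gives the contour back
        rng = np.random.default_rng(seed)
        blob = np.zeros((80, 80), dtype=bool)
        r, c = rng.integers(25, 55, size=2)
        rr, cc = np.ogrid[:80, :80]
        blob |= (rr - r) ** 2 / 180 + (cc - c) ** 2 / 90 <= 1
        from cxrctr.ctr import _contour

        contour = _contour(blob, "blob")
        refilled = ndimage.binary_fill_holes(contour)
        assert np.array_equal(_contour(refilled, "blob"), contour)


class TestFindDomeRow:
    def test_phantom_apex_within_one_row(self, default_phantom):
        # noise-free raster: use the raw contour, no smoothing involved
        mask, truth = default_phantom
        b = extract_boundary(mask)
        dome, trace = find_dome_row(b.right_lung)
        assert abs(dome - truth.dome_row) <= 1
        rows = sorted(trace)
        assert all(trace[r] > 0 for r in rows)

    def test_flat_bottom_rectangle_is_ambiguous(self):
        mask = rectangular_lung_mask()
        b = extract_boundary(mask)  # no smoothing: corners stay square
        with pytest.raises(CTRError, match="flat diaphragm"):
            find_dome_row(b.right_lung)

    def test_translation_shifts_dome_exactly(self, default_phantom):
        mask, _ = default_phantom
        b = extract_boundary(clean_mask(mask))
        dome, _ = find_dome_row(b.right_lung)
        shifted = np.zeros_like(b.right_lung)
        shifted[10:, :] = b.right_lung[:-10, :]
        dome_shifted, _ = find_dome_row(shifted)
        assert dome_shifted == dome + 10

    def test_empty_contour_undetectable(self):
        with pytest.raises(CTRError, match="dome undetectable"):
            find_dome_row(np.zeros((32, 32), dtype=bool))


class TestDiameters:
    def test_two_rectangles_L(self):
        # lungs spanning cols [10,40) and [60,90): extremes at pixel centers 10, 89
        labels = np.zeros((100, 100), dtype=np.uint8)
        labels[20:80, 10:40] = LUNG
        labels[20:80, 60:90] = LUNG
        labels[50:70, 45:55] = HEART
        b = extract_boundary(SegmentationMask(labels))
        L, endpoints = thoracic_diameter(b.all_lungs, 50)
        assert L == 79.0
        assert endpoints == ((50, 10), (50, 89))

    def test_mirrored_mask_same_L(self):
        labels = np.zeros((100, 100), dtype=np.uint8)
        labels[20:80, 10:40] = LUNG
        labels[20:80, 55:95] = LUNG
        labels[50:70, 43:52] = HEART
        b = extract_boundary(SegmentationMask(labels))
        bm = extract_boundary(SegmentationMask(labels[:, ::-1].copy()))
        assert thoracic_diameter(b.all_lungs, 40)[0] == thoracic_diameter(bm.all_lungs, 40)[0]

    def test_upscaled_L_doubles(self, default_phantom):
        mask, _ = default_phantom
        b = extract_boundary(clean_mask(mask))
        dome, _ = find_dome_row(b.right_lung)
        L, _ = thoracic_diameter(b.all_lungs, dome)
        up = np.repeat(np.repeat(mask.labels, 2, axis=0), 2, axis=1)
        b2 = extract_boundary(clean_mask(SegmentationMask(up)))
        dome2, _ = find_dome_row(b2.right_lung)
        L2, _ = thoracic_diameter(b2.all_lungs, dome2)
        assert abs(L2 - 2 * L) <= 4  # within 2 source-scale pixels

    def test_tangent_outside_lungs(self):
        mask = two_lung_mask()
        b = extract_boundary(mask)
        with pytest.raises(CTRError, match="tangent outside"):
            thoracic_diameter(b.all_lungs, 60)

    def test_cardiac_halves_about_midline(self):
        # heart spanning cols [35,65): pixel centers 35..64
        labels = np.zeros((100, 100), dtype=np.uint8)
        labels[20:80, 5:30] = LUNG
        labels[20:80, 70:95] = LUNG
        labels[40:70, 35:65] = HEART
        b = extract_boundary(SegmentationMask(labels))
        L1, L2, _, warnings = cardiac_diameter(b.heart, 50)
        assert (L1, L2) == (15.0, 14.0)
        assert warnings == ()

    def test_midline_invariance_inside_extent(self):
        labels = np.zeros((100, 100), dtype=np.uint8)
        labels[20:80, 5:30] = LUNG
        labels[20:80, 70:95] = LUNG
        labels[40:70, 35:65] = HEART
        b = extract_boundary(SegmentationMask(labels))
        totals = {cardiac_diameter(b.heart, m)[0] + cardiac_diameter(b.heart, m)[1]
                  for m in np.arange(35.5, 64.0, 1.5)}
        assert totals == {29.0}

    def test_heart_right_of_midline_warns(self):
        labels = np.zeros((100, 100), dtype=np.uint8)
        labels[20:80, 5:30] = LUNG
        labels[20:80, 70:95] = LUNG
        labels[40:70, 35:65] = HEART
        b = extract_boundary(SegmentationMask(labels))
        L1, L2, _, warnings = cardiac_diameter(b.heart, 20.0)
        assert warnings
        assert L1 + L2 != 29.0


class TestComputeCTR:
    def test_target_ctr_recovered(self):
        rng = np.random.default_rng(42)
        spec = random_phantom_spec(rng, target_ctr=0.45, noisy=False)
        mask, truth = generate_phantom(spec)
        result = compute_ctr(mask)
        assert result.ok
        assert abs(truth.ctr - 0.45) < 0.02  # generator hits its target
        assert abs(result.ctr - truth.ctr) < 0.01

    def test_resized_mask_same_ctr(self, default_phantom):
        mask, _ = default_phantom
        r0 = compute_ctr(mask)
        up = np.repeat(np.repeat(mask.labels, 2, axis=0), 2, axis=1)
        r2 = compute_ctr(SegmentationMask(up))
        assert abs(r2.ctr - r0.ctr) < 0.01

    def test_heart_erased_reports_failure(self, default_phantom):
        mask, _ = default_phantom
        labels = mask.labels.copy()
        labels[labels == HEART] = 0
        result = compute_ctr(SegmentationMask(labels))
        assert not result.ok and result.failure_reason == "heart absent"
        assert result.ctr is None

    def test_deterministic(self, default_phantom):
        mask, _ = default_phantom
        assert compute_ctr(mask) == compute_ctr(mask)

    def test_translation_moves_endpoints_identically(self, default_phantom):
        mask, _ = default_phantom
        r0 = compute_ctr(mask)
        shifted = np.roll(np.roll(mask.labels, 12, axis=0), 5, axis=1)
        r1 = compute_ctr(SegmentationMask(shifted))
        assert r1.ctr == r0.ctr
        for e0, e1 in zip(r0.thoracic_endpoints + r0.cardiac_endpoints,
                          r1.thoracic_endpoints + r1.cardiac_endpoints):
            assert (e1[0] - e0[0], e1[1] - e0[1]) == (12, 5)

    def test_mirroring_preserves_diameters(self, symmetric_phantom):
        mask, _ = symmetric_phantom
        r0 = compute_ctr(mask)
        rm = compute_ctr(SegmentationMask(mask.labels[:, ::-1].copy()))
        assert rm.L == r0.L
        assert rm.L1 + rm.L2 == r0.L1 + r0.L2

    def test_parameter_recovery_batch(self):
        rng = np.random.default_rng(2024)
        errors = []
        for _ in range(40):
            spec = random_phantom_spec(rng)
            mask, truth = generate_phantom(spec)
            result = compute_ctr(mask)
            assert result.ok, result.failure_reason
            errors.append(abs(result.ctr - truth.ctr))
        assert float(np.mean(errors)) < 0.01
        assert float(np.max(errors)) < 0.03


@pytest.mark.parametrize("value,expected", [(0.56, True), (0.55, False), (0.40, False)])
def test_cardiomegaly_strict_threshold(value, expected):
    assert classify_cardiomegaly(value) is expected


def test_cardiomegaly_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_cardiomegaly(0.0)
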