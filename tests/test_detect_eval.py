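"""Detection scoring: IoU, matching, PR/AP, Wilson intervals, FP-per-image."""

import math

import numpy as np
import pytest

from cxrctr.annot_io import BoundingBox, ImageAnnotation
from cxrctr.detect_eval import (
    PRCurve,
    average_precision,
    box_iou,
    evaluate,
    fp_per_image,
    match_boxes,
    mean_ap,
    operating_point_metrics,
    pr_curve,
    wilson_interval,
)
from cxrctr.detect_eval import _curve_from_verdicts, PredictionVerdict


def bb(x0, y0, x1, y1, cat="a", conf=None):
    return BoundingBox(cat, x0, y0, x1, y1, conf)


def ann(boxes, image_id="i1", size=1000):
    return ImageAnnotation(image_id, size, size, tuple(boxes))


def pixel_iou_oracle(a: BoundingBox, b: BoundingBox) -> float:
    """Count pixels on the discrete grid; exact for integer boxes."""
    grid_a = {(x, y) for x in range(int(a.x_min), int(a.x_max))
              for y in range(int(a.y_min), int(a.y_max))}
    grid_b = {(x, y) for x in range(int(b.x_min), int(b.x_max))
              for y in range(int(b.y_min), int(b.y_max))}
    return len(grid_a & grid_b) / len(grid_a | grid_b)


class TestBoxIoU:
    def test_identity_disjoint_and_overlap(self):
        assert box_iou(bb(0, 0, 10, 10), bb(0, 0, 10, 10)) == 1.0
        assert box_iou(bb(0, 0, 10, 10), bb(20, 20, 30, 30)) == 0.0
        assert box_iou(bb(0, 0, 10, 10), bb(5, 0, 15, 10)) == pytest.approx(50 / 150)

    def test_matches_pixel_enumeration_oracle(self):
        rng = np.random.default_rng(314)
        for _ in range(60):
            x0, y0, x1, y1 = *rng.integers(0, 40, 2), *rng.integers(41, 51, 2)
            u0, v0, u1, v1 = *rng.integers(0, 40, 2), *rng.integers(41, 51, 2)
            a, b = bb(x0, y0, x1, y1), bb(u0, v0, u1, v1)
            assert box_iou(a, b) == pixel_iou_oracle(a, b)
            assert box_iou(a, b) == box_iou(b, a)  # symmetry
            assert 0.0 <= box_iou(a, b) <= 1.0

    def test_zero_area_rejected(self):
        box = bb(0, 0, 10, 10)
        object.__setattr__(box, "x_max", 0.0)  # bypass constructor check
        with pytest.raises(ValueError):
            box_iou(box, bb(0, 0, 5, 5))


class TestMatching:
    def test_one_gt_two_overlapping_preds(self):
        gt = [ann([bb(10, 10, 30, 30)])]
        preds = [ann([bb(10, 10, 30, 30, conf=0.9), bb(11, 10, 31, 30, conf=0.8)])]
        m = match_boxes(preds, gt, 0.5)
        by_conf = {v.confidence: v.is_tp for v in m.verdicts}
        assert by_conf == {0.9: True, 0.8: False}

    def test_cross_category_never_matches(self):
        gt = [ann([bb(10, 10, 30, 30, cat="b")])]
        preds = [ann([bb(10, 10, 30, 30, cat="a", conf=0.9)])]
        m = match_boxes(preds, gt, 0.1)
        assert m.tp == 0 and m.fp == 1 and m.fn == 1

    def test_no_predictions(self):
        gt = [ann([bb(10, 10, 30, 30)])]
        m = match_boxes([ann([], "i1")], gt, 0.5)
        assert m.tp == 0 and m.fp == 0 and m.fn == 1

    def test_missing_confidence_rejected(self):
        gt = [ann([bb(10, 10, 30, 30)])]
        with pytest.raises(ValueError, match="confidence"):
            match_boxes([ann([bb(10, 10, 30, 30)])], gt, 0.5)

    def test_one_to_one_bound(self):
        rng = np.random.default_rng(8)
        gt = [ann([bb(*sorted(rng.integers(0, 400, 2)), *sorted(rng.integers(401, 800, 2)))
                   for _ in range(6)])]
        preds = [ann([bb(*sorted(rng.integers(0, 400, 2)), *sorted(rng.integers(401, 800, 2)),
                         conf=float(rng.uniform(0.1, 0.9))) for _ in range(9)])]
        m = match_boxes(preds, gt, 0.3)
        assert m.tp <= min(9, 6)
        matched = [v.matched_gt for v in m.verdicts if v.is_tp]
        assert len(matched) == len(set(matched))  # each GT claimed once


class TestPRCurve:
    GT = [ann([bb(10, 10, 30, 30)])]

    def test_perfect_detector(self):
        preds = [ann([bb(10, 10, 30, 30, conf=0.9)])]
        c = pr_curve(preds, self.GT, 0.5, "a")
        assert c.precision == (1.0,) and c.recall == (1.0,)
        assert average_precision(c) == 1.0

    def test_tp_then_fp(self):
        preds = [ann([bb(10, 10, 30, 30, conf=0.9), bb(500, 500, 600, 600, conf=0.8)])]
        c = pr_curve(preds, self.GT, 0.5, "a")
        assert list(zip(c.precision, c.recall)) == [(1.0, 1.0), (0.5, 1.0)]

    def test_fp_then_tp(self):
        preds = [ann([bb(500, 500, 600, 600, conf=0.9), bb(10, 10, 30, 30, conf=0.8)])]
        c = pr_curve(preds, self.GT, 0.5, "a")
        assert list(zip(c.precision, c.recall)) == [(0.0, 0.0), (0.5, 1.0)]
        assert average_precision(c) == 0.5

    def test_zero_gt_category_rejected(self):
        preds = [ann([bb(10, 10, 30, 30, conf=0.9, cat="zz")])]
        with pytest.raises(ValueError, match="no ground-truth"):
            pr_curve(preds, self.GT, 0.5, "zz")


def brute_force_ap(verdicts, n_gt):
    """Independent AP: enumerate thresholds, then integrate the precision
    envelope over recall by direct max-scanning."""
    confs = sorted({v.confidence for v in verdicts}, reverse=True)
    pts = []
    for thr in confs:
        kept = [v for v in verdicts if v.confidence >= thr]
        tp = sum(v.is_tp for v in kept)
        pts.append((tp / len(kept), tp / n_gt))
    ap, prev_r = 0.0, 0.0
    for _, r in sorted(pts, key=lambda t: t[1]):
        if r <= prev_r:
            continue
        best_p = max(p for p, rr in pts if rr >= r - 1e-12)
        ap += (r - prev_r) * best_p
        prev_r = r
    return ap


class TestAveragePrecision:
    def test_zero_tp_curve(self):
        c = PRCurve("a", (0.0, 0.0), (0.0, 0.0), (0.9, 0.5), n_gt=2)
        assert average_precision(c) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        n_gt = int(rng.integers(1, 10))
        n_tp = int(rng.integers(0, min(n, n_gt) + 1))
        flags = np.array([True] * n_tp + [False] * (n - n_tp))
        rng.shuffle(flags)
        confs = np.round(rng.uniform(0.05, 0.95, n), 2)  # duplicates likely
        verdicts = [PredictionVerdict("i", "a", float(c), bool(f), None, 0.0)
                    for c, f in zip(confs, flags)]
        curve = _curve_from_verdicts(verdicts, n_gt, "a")
        for method in ("all-point",):
            assert average_precision(curve, method) == pytest.approx(
                brute_force_ap(verdicts, n_gt), abs=1e-12)

    def test_eleven_point_variant_bounded(self):
        verdicts = [PredictionVerdict("i", "a", 0.9, True, None, 0.0),
                    PredictionVerdict("i", "a", 0.7, False, None, 0.0)]
        curve = _curve_from_verdicts(verdicts, 2, "a")
        assert 0.0 <= average_precision(curve, "11-point") <= 1.0

    def test_monotone_in_iou_threshold(self):
        from cxrctr.synthetic import ScenarioSpec, generate_detection_scenario

        gts, preds, _ = generate_detection_scenario(
            ScenarioSpec(n_images=60, hit_probability=0.9, fp_rate=0.3,
                         localization_jitter=25.0, seed=5))
        report = evaluate(preds, gts, iou_thresholds=(0.1, 0.3, 0.5, 0.7))
        maps = [report.map_per_threshold[t] for t in (0.1, 0.3, 0.5, 0.7)]
        assert all(m1 >= m2 - 1e-12 for m1, m2 in zip(maps, maps[1:]))


class TestMeanAP:
    def test_arithmetic(self):
        assert mean_ap({"a": 0.5, "b": 0.5}) == 0.5
        assert mean_ap({"a": 1.0, "b": 0.0}) == 0.5

    def test_seeded_values_match_independent_sum(self):
        rng = np.random.default_rng(14)
        aps = {f"c{i}": float(rng.uniform()) for i in range(14)}
        total = 0.0
        for v in aps.values():
            total += v
        assert mean_ap(aps) == pytest.approx(total / 14, abs=1e-15)

    def test_excluded_categories_ignored(self):
        assert mean_ap({"a": 0.8, "b": None}) == 0.8
        with pytest.raises(ValueError):
            mean_ap({"a": None})


class TestOperatingPoint:
    def _match(self, tp, fp, fn):
        verdicts = tuple(
            PredictionVerdict("i", "a", 0.9, k < tp, ("i", k) if k < tp else None, 0.9)
            for k in range(tp + fp))
        from cxrctr.detect_eval import MatchResult

        return MatchResult(0.5, verdicts, {"a": tp + fn}, n_images=1)

    def test_perfect(self):
        m = self._match(5, 0, 0)
        out = operating_point_metrics(m)
        assert out["precision"] == out["recall"] == out["f1"] == 1.0

    def test_all_wrong(self):
        out = operating_point_metrics(self._match(0, 3, 2))
        assert out["precision"] == 0.0 and out["recall"] == 0.0 and out["f1"] == 0.0

    def test_hand_arithmetic(self):
        out = operating_point_metrics(self._match(6, 4, 2))
        assert out["precision"] == pytest.approx(0.6)
        assert out["recall"] == pytest.approx(0.75)
        assert out["f1"] == pytest.approx(2 * 0.45 / 1.35)

    def test_no_predictions_undefined_precision(self):
        out = operating_point_metrics(self._match(0, 0, 3))
        assert out["precision"] is None and out["fn"] == 3


class TestWilson:
    def test_boundaries(self):
        lo, _ = wilson_interval(0, 10)
        _, hi = wilson_interval(10, 10)
        assert lo == 0.0 and hi == 1.0

    def test_closed_form_oracle(self):
        # direct evaluation of the Wilson score formula
        z = 1.959963984540054
        s, n = 5, 10
        p = s / n
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        lo, hi = wilson_interval(s, n)
        assert lo == pytest.approx(center - half, abs=1e-9)
        assert hi == pytest.approx(center + half, abs=1e-9)
        assert (round(lo, 3), round(hi, 3)) == (0.237, 0.763)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_interval(1, 0)
        with pytest.raises(ValueError):
            wilson_interval(5, 3)


class TestFPPerImage:
    def test_zero_and_simple_rate(self):
        gt = [ann([], f"i{k}") for k in range(5)]
        preds = [ann([bb(10, 10, 30, 30, conf=0.5) for _ in range(2)], f"i{k}")
                 for k in range(5)]
        m = match_boxes(preds, gt, 0.5)
        rates = fp_per_image(m)
        assert rates["__overall__"] == 2.0
        m0 = match_boxes([ann([], f"i{k}") for k in range(5)], gt, 0.5)
        assert fp_per_image(m0)["__overall__"] == 0.0

    def test_poisson_rate_recovered(self):
        from cxrctr.synthetic import ScenarioSpec, generate_detection_scenario

        lam = 0.5
        spec = ScenarioSpec(n_images=400, hit_probability=1.0, fp_rate=lam / 14,
                            seed=3)
        gts, preds, _ = generate_detection_scenario(spec)
        m = match_boxes(preds, gts, 0.5)
        rate = fp_per_image(m)["__overall__"]
        se = math.sqrt(lam / 400)
        assert abs(rate - lam) < 3 * se
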