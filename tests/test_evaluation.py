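import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fovod.evaluation import (CostLedger, average_precision, iou, iou_matrix,
                              mean_ap, nms, relative_cost)
from fovod import reference


class TestIou:
    def test_identical(self):
        assert iou((10, 10, 3, 4), (10, 10, 3, 4)) == 1.0

    def test_disjoint(self):
        assert iou((10, 10, 0, 0), (10, 10, 100, 100)) == 0.0

    def test_half_shift(self):
        # 10x10 boxes offset by 5: overlap 50, union 150
        assert iou((10, 10, 0, 0), (10, 10, 5, 0)) == pytest.approx(1 / 3)

    def test_zero_area(self):
        assert iou((0, 10, 0, 0), (10, 10, 0, 0)) == 0.0

    @given(st.lists(st.floats(1, 50), min_size=8, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, vals):
        a = (vals[0], vals[1], vals[2], vals[3])
        b = (vals[4], vals[5], vals[6], vals[7])
        v = iou(a, b)
        assert v == pytest.approx(iou(b, a))
        assert 0.0 <= v <= 1.0

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(0)
        boxes = np.column_stack([rng.uniform(1, 20, (12, 2)),
                                 rng.uniform(0, 30, (12, 2))])
        m = iou_matrix(boxes, boxes)
        for i in range(12):
            for j in range(12):
                assert m[i, j] == pytest.approx(iou(boxes[i], boxes[j]))


def _nms_reference(dets, thresh):
    """Independent O(n^2) greedy reference."""
    rest = sorted(dets, key=lambda d: -d[0])
    kept = []
    while rest:
        best = rest.pop(0)
        kept.append(best)
        rest = [d for d in rest if iou(best[1], d[1]) <= thresh]
    return kept


class TestNms:
    def test_duplicate_keeps_higher_score(self):
        out = nms([(2.0, (10, 10, 0, 0)), (1.0, (10, 10, 0, 0))])
        assert out == [(2.0, (10, 10, 0, 0))]

    def test_disjoint_unchanged(self):
        dets = [(3.0, (5, 5, 0, 0)), (2.0, (5, 5, 50, 50)),
                (1.0, (5, 5, 100, 0))]
        assert nms(dets) == dets

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_quadratic_reference(self, seed):
        rng = np.random.default_rng(seed)
        dets = [(float(rng.normal()), tuple(np.r_[rng.uniform(5, 20, 2),
                                                  rng.uniform(0, 40, 2)]))
                for _ in range(40)]
        assert nms(dets, 0.5) == _nms_reference(dets, 0.5)


def _ap_reference(dets, gt, thresh=0.5):
    """Exhaustive threshold sweep with fresh greedy matching per threshold."""
    scores = sorted({s for _, s, _ in dets}, reverse=True)
    n_gt = sum(len(v) for v in gt.values())
    pts = [(0.0, None)]
    rp = []
    for t in scores:
        sel = sorted([d for d in dets if d[1] >= t], key=lambda d: -d[1])
        matched = {k: [False] * len(v) for k, v in gt.items()}
        tp = fp = 0
        for img, _, box in sel:
            best, bj = 0.0, -1
            for j, g in enumerate(gt.get(img, [])):
                v = iou(box, g)
                if v > best:
                    best, bj = v, j
            if best > thresh and not matched[img][bj]:
                matched[img][bj] = True
                tp += 1
            else:
                fp += 1
        rp.append((tp / n_gt, tp / max(tp + fp, 1)))
    r = np.array([0.0] + [x[0] for x in rp])
    p = np.array([rp[0][1]] + [x[1] for x in rp])
    return 100.0 * np.trapezoid(p, r)


class TestAveragePrecision:
    def test_perfect_detector(self):
        gt = {"a": [(10, 10, 0, 0)], "b": [(8, 12, 5, 5)]}
        dets = [("a", 2.0, (10, 10, 0, 0)), ("b", 1.5, (8, 12, 5, 5))]
        assert average_precision(dets, gt).ap == pytest.approx(100.0)

    def test_no_detections(self):
        assert average_precision([], {"a": [(10, 10, 0, 0)]}).ap == 0.0

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            average_precision([("a", 1.0, (5, 5, 0, 0))], {"a": []})

    def test_toy_case_matches_exhaustive_sweep(self):
        gt = {"a": [(10, 10, 0, 0), (10, 10, 30, 0)], "b": [(10, 10, 5, 5)]}
        dets = [("a", 5.0, (10, 10, 1, 0)),    # TP
                ("a", 4.0, (10, 10, 50, 50)),  # FP
                ("b", 3.0, (10, 10, 5, 6)),    # TP
                ("a", 2.0, (10, 10, 29, 1)),   # TP
                ("a", 1.0, (10, 10, 2, 1))]    # duplicate -> FP
        pr = average_precision(dets, gt)
        assert pr.ap == pytest.approx(_ap_reference(dets, gt), abs=1e-9)

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(3)
        gt = {i: [(12, 12, float(rng.uniform(0, 30)), 5.0)] for i in range(8)}
        dets = []
        for i in range(8):
            for _ in range(4):
                dets.append((i, float(rng.normal()),
                             (12, 12, float(rng.uniform(0, 30)), 5.0)))
        ap1 = average_precision(dets, gt).ap
        ap2 = average_precision([(i, np.exp(s) + 7, b) for i, s, b in dets],
                                gt).ap
        assert ap1 == pytest.approx(ap2)

    def test_true_positives_bounded_by_ground_truth(self):
        gt = {"a": [(10, 10, 0, 0)]}
        dets = [("a", s, (10, 10, 0, 0)) for s in (3.0, 2.0, 1.0)]
        pr = average_precision(dets, gt)
        assert pr.recall.max() <= 1.0

    def test_11point_variant_runs(self):
        gt = {"a": [(10, 10, 0, 0)]}
        dets = [("a", 1.0, (10, 10, 0, 0))]
        assert average_precision(dets, gt, method="11point").ap == \
            pytest.approx(100.0)


class TestMeanAp:
    def test_single_class_identity(self):
        assert mean_ap([42.0]) == 42.0

    def test_all_equal(self):
        assert mean_ap([7.0] * 5) == pytest.approx(7.0)

    def test_benchmark_sw_row(self):
        assert reference.sw_mean_ap() == pytest.approx(17.1, abs=0.05)


class TestCostLedger:
    def test_template_cost_6x8(self):
        assert CostLedger.template_cost(6, 8) == 48

    def test_accumulation_and_stages(self):
        led = CostLedger()
        led.add(10, "sw")
        led.add(5, "fod")
        assert led.ops == 15
        assert led.by_stage == {"sw": 10.0, "fod": 5.0}

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            CostLedger().add(-1)

    def test_relative_cost(self):
        assert relative_cost(50, 50) == pytest.approx(100.0)
        assert relative_cost(10, 100) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            relative_cost(1, 0)
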