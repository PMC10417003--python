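import numpy as np
import pytest

from pigcloud.errors import UndefinedMetricError
from pigcloud.evaluation import (
    ConfusionCounts,
    Detection,
    GroundTruth,
    IOU_THRESHOLDS,
    SegConfusionMatrix,
    box_iou,
    filter_by_confidence,
    global_accuracy,
    map_over_range,
    mask_iou,
    match_and_ap,
    precision,
)

from oracles import ap_enumeration_oracle, random_toy_detections


class TestPrecision:
    @pytest.mark.parametrize(
        "tp,fp,expected", [(9, 1, 0.9), (0, 5, 0.0), (7, 0, 1.0)]
    )
    def test_direct_formula(self, tp, fp, expected):
        assert precision(ConfusionCounts(TP=tp, FP=fp)) == pytest.approx(expected)

    def test_undefined_without_positive_predictions(self):
        with pytest.raises(UndefinedMetricError):
            precision(ConfusionCounts(TP=0, FP=0, FN=3))


class TestIoU:
    def test_identical_boxes(self):
        assert box_iou((0, 0, 4, 4), (0, 0, 4, 4)) == 1.0

    def test_disjoint_boxes(self):
        assert box_iou((0, 0, 2, 2), (5, 5, 7, 7)) == 0.0

    def test_hand_computed_overlap(self):
        # intersection 2, union 6
        assert box_iou((0, 0, 2, 2), (1, 0, 3, 2)) == pytest.approx(1 / 3)

    def test_mask_iou_matches_pixel_sets(self, rng):
        a = rng.random((20, 20)) > 0.5
        b = rng.random((20, 20)) > 0.5
        expected = np.sum(a & b) / np.sum(a | b)
        assert mask_iou(a, b) == pytest.approx(expected)

    def test_empty_pair_undefined(self):
        with pytest.raises(UndefinedMetricError):
            mask_iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool))


class TestMatchAndAP:
    def _gts(self, n):
        return [GroundTruth(box=(i * 20.0, 0.0, i * 20.0 + 10, 10.0)) for i in range(n)]

    def test_perfect_detections_ap_one(self):
        gts = self._gts(4)
        dets = [Detection(box=g.box, score=0.95) for g in gts]
        for t in IOU_THRESHOLDS:
            ap, counts = match_and_ap(dets, gts, float(t))
            assert ap == 1.0
            assert counts.TP == 4 and counts.FP == 0 and counts.FN == 0

    def test_hand_enumerated_pr_curve(self):
        """3 gts, dets (.9 TP, .8 FP, .7 TP, .6 TP): AP by hand = 23/30."""
        gts = self._gts(3)
        far = (500.0, 500.0, 510.0, 510.0)
        dets = [
            Detection(box=gts[0].box, score=0.9),
            Detection(box=far, score=0.8),
            Detection(box=gts[1].box, score=0.7),
            Detection(box=gts[2].box, score=0.6),
        ]
        # PR points: (1/3,1), (1/3,1/2), (2/3,2/3), (1,3/4);
        # envelope: p=1 up to r=1/3, then 3/4 up to r=1.
        expected = (1 / 3) * 1.0 + (2 / 3) * (3 / 4)
        ap, _ = match_and_ap(dets, gts, 0.5)
        assert ap == pytest.approx(expected, abs=1e-12)
        assert ap == pytest.approx(ap_enumeration_oracle(dets, gts, 0.5), abs=1e-12)

    def test_duplicate_detections_single_tp(self):
        gts = self._gts(1)
        dets = [Detection(box=gts[0].box, score=s) for s in (0.9, 0.8, 0.7)]
        _, counts = match_and_ap(dets, gts, 0.5)
        assert counts.TP == 1 and counts.FP == 2

    def test_empty_gts_all_fp(self):
        dets = [Detection(box=(0, 0, 5, 5), score=0.9)]
        ap, counts = match_and_ap(dets, [], 0.5)
        assert ap == 0.0 and counts.FP == 1

    def test_empty_dets(self):
        ap, counts = match_and_ap([], self._gts(2), 0.5)
        assert ap == 0.0 and counts.FN == 2

    def test_score_rescaling_invariance(self):
        gts = self._gts(3)
        dets = [
            Detection(box=gts[0].box, score=0.9),
            Detection(box=(500, 500, 510, 510), score=0.5),
            Detection(box=gts[1].box, score=0.3),
        ]
        squashed = [Detection(box=d.box, score=d.score**3) for d in dets]
        for t in (0.5, 0.75):
            assert match_and_ap(dets, gts, t)[0] == match_and_ap(squashed, gts, t)[0]

    @pytest.mark.parametrize("seed", range(200))
    def test_matches_enumeration_oracle_on_toy_scenes(self, seed):
        """200 seeded toy scenes: AP equals the exhaustive PR oracle to 1e-9."""
        dets, gts = random_toy_detections(seed)
        for t in IOU_THRESHOLDS:
            ap, _ = match_and_ap(dets, gts, float(t))
            assert ap == pytest.approx(ap_enumeration_oracle(dets, gts, float(t)), abs=1e-9)

    def test_ap_non_increasing_in_threshold(self):
        for seed in range(30):
            dets, gts = random_toy_detections(seed + 1000)
            aps = [match_and_ap(dets, gts, float(t))[0] for t in IOU_THRESHOLDS]
            assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))


class TestMapOverRange:
    def test_perfect_detections(self):
        gts = [GroundTruth(box=(0, 0, 10, 10))]
        dets = [Detection(box=(0, 0, 10, 10), score=0.99)]
        r = map_over_range(dets, gts)
        assert r.map50 == 1.0 and r.map5095 == 1.0

    def test_iou_point_six_sweep(self):
        """IoU exactly 0.6 on every gt: AP 1 at thresholds <= 0.6, else 0; mean 0.3."""
        gts = [GroundTruth(box=(i * 30.0, 0.0, i * 30.0 + 10, 10.0)) for i in range(3)]
        dets = [
            Detection(box=(g.box[0], g.box[1], g.box[2], g.box[1] + 6.0), score=0.9)
            for g in gts
        ]
        r = map_over_range(dets, gts)
        for t in IOU_THRESHOLDS:
            assert r.per_threshold[float(t)] == (1.0 if t <= 0.6 else 0.0)
        assert r.map5095 == pytest.approx(0.3, abs=1e-12)

    def test_no_detections_zero_everywhere(self):
        r = map_over_range([], [GroundTruth(box=(0, 0, 5, 5))])
        assert all(v == 0.0 for v in r.per_threshold.values())

    def test_coco101_close_to_continuous(self):
        dets, gts = random_toy_detections(7)
        a = map_over_range(dets, gts, interpolation="continuous").map5095
        b = map_over_range(dets, gts, interpolation="coco101").map5095
        assert abs(a - b) < 0.05


class TestGlobalAccuracy:
    def test_diagonal_matrix(self):
        assert global_accuracy(SegConfusionMatrix(p=np.diag([5, 9]))) == 1.0

    def test_hand_computed_two_class(self):
        m = SegConfusionMatrix(p=[[90, 10], [20, 80]])
        assert global_accuracy(m) == pytest.approx(0.85)

    def test_all_off_diagonal(self):
        assert global_accuracy(SegConfusionMatrix(p=[[0, 3], [4, 0]])) == 0.0

    def test_empty_undefined(self):
        with pytest.raises(UndefinedMetricError):
            global_accuracy(SegConfusionMatrix(p=np.zeros((2, 2), int)))

    def test_from_label_images(self, rng):
        truth = rng.integers(0, 2, (30, 30))
        pred = rng.integers(0, 2, (30, 30))
        m = SegConfusionMatrix.from_label_images(truth, pred, 2)
        assert m.p.sum() == 900
        assert global_accuracy(m) == pytest.approx(np.mean(truth == pred))


class TestConfidenceFilter:
    def test_operating_threshold_only_affects_counts(self):
        gts = [GroundTruth(box=(0, 0, 10, 10)), GroundTruth(box=(30, 0, 40, 10))]
        dets = [
            Detection(box=gts[0].box, score=0.95),
            Detection(box=gts[1].box, score=0.5),
        ]
        ap_all, counts_all = match_and_ap(dets, gts, 0.5)
        ap_op, counts_op = match_and_ap(dets, gts, 0.5, conf_threshold=0.9)
        assert ap_op == ap_all == 1.0  # AP sweeps all scores
        assert counts_all.TP == 2
        assert counts_op.TP == 1 and counts_op.FN == 1

    def test_filter_keeps_strictly_above(self):
        dets = [Detection(box=(0, 0, 2, 2), score=s) for s in (0.89, 0.9, 0.91)]
        assert [d.score for d in filter_by_confidence(dets)] == [0.91]
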