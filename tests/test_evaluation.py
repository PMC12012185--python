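"""Detection evaluation engine: matching, PR curves, 101-point AP, agreement.

The independent oracle used throughout is an exhaustive confidence-threshold
sweep: every distinct confidence defines an operating point (recall,
precision); interpolated precision at recall level r is the maximum
precision over operating points with recall >= r; AP is the mean over the
101 levels 0.00..1.00.  It shares no code with the production path, which
walks the ranked cumulative curve instead.
"""

import math

import numpy as np
import pytest

import stomakit as sk
from stomakit import (
    Box,
    DetectionSet,
    GroundTruthSet,
    ValidationError,
    average_precision,
    counting_agreement,
    map50,
    match_detections,
    pr_curve,
)
from stomakit.evaluation import MatchLabels, iou


def sweep_oracle_ap(confidences, tp_flags, n_gt) -> float:
    """Brute-force AP via explicit threshold enumeration (test-only oracle)."""
    if n_gt == 0:
        return 1.0 if not confidences else 0.0
    points = []
    for t in sorted(set(confidences)):
        keep = [f for c, f in zip(confidences, tp_flags) if c >= t]
        if not keep:
            continue
        tp = sum(keep)
        points.append((tp / n_gt, tp / len(keep)))
    total = 0.0
    for level in [k / 100 for k in range(101)]:
        best = 0.0
        for r, p in points:
            if r >= level and p > best:
                best = p
        total += best
    return total / 101


def random_instance(rng):
    """Random micro-instance: distinct confidences, feasible TP pattern."""
    n_det = int(rng.integers(0, 7))
    n_gt = int(rng.integers(1, 5))
    confs = list(np.round(rng.choice(np.arange(1, 1000), n_det, replace=False) / 1000, 3))
    max_tp = min(n_det, n_gt)
    n_tp = int(rng.integers(0, max_tp + 1))
    flags = [True] * n_tp + [False] * (n_det - n_tp)
    rng.shuffle(flags)
    return confs, flags, n_gt


class TestIoU:
    def test_worked_cases(self):
        assert iou(Box(0, 0, 10, 10), Box(0, 0, 10, 10)) == 1.0
        assert iou(Box(0, 0, 10, 10), Box(30, 30, 40, 40)) == 0.0
        assert iou(Box(0, 0, 10, 10), Box(5, 0, 15, 10)) == pytest.approx(1 / 3)


class TestMatchDetections:
    def test_perfect_detection_is_tp(self):
        gt = [Box(0, 0, 10, 10)]
        labels = match_detections([Box(0, 0, 10, 10, 0.9)], gt, 0.5)
        assert labels.tp == (True,)
        assert labels.gt_matched == (True,)

    def test_single_match_rule(self):
        # two detections over one ground truth: only the higher-confidence
        # one becomes a true positive
        gt = [Box(0, 0, 10, 10)]
        dets = [Box(0, 0, 10, 10, 0.7), Box(1, 0, 11, 10, 0.9)]
        labels = match_detections(dets, gt, 0.5)
        assert labels.tp == (True, False)
        assert labels.confidences == (0.9, 0.7)

    def test_worked_three_detections_two_gts(self):
        # ranked: conf 0.9 hits gt0 (TP), 0.8 misses everything (FP),
        # 0.7 hits gt1 (TP) -> labels [TP, FP, TP]
        gts = [Box(0, 0, 10, 10), Box(40, 0, 50, 10)]
        dets = [
            Box(0, 0, 10, 10, 0.9),
            Box(20, 20, 30, 30, 0.8),
            Box(40, 0, 50, 10, 0.7),
        ]
        labels = match_detections(dets, gts, 0.5)
        assert labels.tp == (True, False, True)

    def test_detection_claims_highest_iou_gt(self):
        gts = [Box(0, 0, 10, 10), Box(6, 0, 16, 10)]
        det = Box(5, 0, 15, 10, 0.9)  # IoU 1/3 with gt0, 9/11 with gt1
        labels = match_detections([det], gts, 0.3)
        assert labels.gt_matched == (False, True)

    def test_iou_tie_resolves_to_lowest_gt_index(self):
        gts = [Box(0, 0, 10, 10), Box(10, 0, 20, 10)]
        det = Box(5, 0, 15, 10, 0.9)  # symmetric overlap with both
        labels = match_detections([det], gts, 0.3)
        assert labels.gt_matched == (True, False)

    def test_threshold_validation(self):
        with pytest.raises(ValidationError):
            match_detections([], [], 0.0)


class TestPRCurve:
    def test_all_true_positives(self):
        labels = MatchLabels((0.9, 0.8), (True, True), (True, True), 0.5)
        curve = pr_curve(labels)
        assert curve.precision == (1.0, 1.0)
        assert curve.recall == (0.5, 1.0)

    def test_all_false_positives(self):
        labels = MatchLabels((0.9, 0.8), (False, False), (False,), 0.5)
        curve = pr_curve(labels)
        assert curve.recall == (0.0, 0.0)
        assert curve.precision == (0.0, 0.0)

    def test_worked_case(self):
        labels = MatchLabels((0.9, 0.8, 0.7), (True, False, True), (True, True), 0.5)
        curve = pr_curve(labels)
        assert curve.precision == pytest.approx((1.0, 0.5, 2 / 3))
        assert curve.recall == pytest.approx((0.5, 0.5, 1.0))

    def test_detections_without_ground_truth_rejected(self):
        labels = MatchLabels((0.9,), (False,), (), 0.5)
        with pytest.raises(ValidationError, match="undefined"):
            pr_curve(labels)

    def test_recall_is_non_decreasing(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            confs, flags, n_gt = random_instance(rng)
            order = np.argsort(confs)[::-1]
            labels = MatchLabels(
                tuple(confs[i] for i in order),
                tuple(flags[i] for i in order),
                (False,) * n_gt,
                0.5,
            )
            rec = pr_curve(labels).recall
            assert all(a <= b for a, b in zip(rec, rec[1:]))


class TestAveragePrecision:
    def test_perfect_detector(self):
        labels = MatchLabels((0.9, 0.8), (True, True), (True, True), 0.5)
        assert average_precision(pr_curve(labels)).ap == pytest.approx(1.0)

    def test_no_true_positives(self):
        labels = MatchLabels((0.9,), (False,), (False, False), 0.5)
        assert average_precision(pr_curve(labels)).ap == 0.0

    def test_worked_101_point_value(self):
        # P=[1, 1/2, 2/3], R=[1/2, 1/2, 1]: envelope is 1.0 up to recall
        # 0.50 (51 levels) and 2/3 beyond (50 levels)
        labels = MatchLabels((0.9, 0.8, 0.7), (True, False, True), (True, True), 0.5)
        expected = (51 * 1.0 + 50 * (2 / 3)) / 101
        assert expected == pytest.approx(0.8350, abs=5e-5)
        assert average_precision(pr_curve(labels)).ap == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_sweep_oracle_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(300):
            confs, flags, n_gt = random_instance(rng)
            order = np.argsort(confs)[::-1]
            labels = MatchLabels(
                tuple(confs[i] for i in order),
                tuple(flags[i] for i in order),
                tuple([True] * sum(flags) + [False] * (n_gt - sum(flags))),
                0.5,
            )
            fast = average_precision(pr_curve(labels)).ap
            oracle = sweep_oracle_ap(confs, flags, n_gt)
            assert fast == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_partition_across_images(self):
        rng = np.random.default_rng(77)
        confs, flags, n_gt = (0.9, 0.6, 0.5, 0.3), (True, False, True, True), 5
        pooled = MatchLabels(confs, flags, (False,) * n_gt, 0.5)
        split_a = MatchLabels(confs[:2], flags[:2], (False,) * 2, 0.5)
        split_b = MatchLabels(confs[2:], flags[2:], (False,) * 3, 0.5)
        ap_pooled = average_precision(pr_curve(pooled)).ap
        ap_split = average_precision(pr_curve([split_a, split_b])).ap
        assert ap_split == pytest.approx(ap_pooled, abs=1e-15)

    def test_deleting_a_true_positive_never_increases_ap(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 60:
            confs, flags, n_gt = random_instance(rng)
            if not any(flags):
                continue
            order = np.argsort(confs)[::-1]
            confs_r = [confs[i] for i in order]
            flags_r = [flags[i] for i in order]
            base = average_precision(
                pr_curve(MatchLabels(tuple(confs_r), tuple(flags_r), (False,) * n_gt, 0.5))
            ).ap
            k = flags_r.index(True)
            reduced = average_precision(
                pr_curve(
                    MatchLabels(
                        tuple(confs_r[:k] + confs_r[k + 1:]),
                        tuple(flags_r[:k] + flags_r[k + 1:]),
                        (False,) * n_gt,
                        0.5,
                    )
                )
            ).ap
            assert reduced <= base + 1e-12
            checked += 1


class TestMap50:
    def test_detections_equal_ground_truth(self):
        gts = GroundTruthSet({"a": [Box(0, 0, 10, 10), Box(20, 0, 30, 10)]})
        dets = DetectionSet(
            {"a": [Box(0, 0, 10, 10, 1.0), Box(20, 0, 30, 10, 1.0)]}
        )
        assert map50(dets, gts) == pytest.approx(1.0)

    def test_unannotated_image_contributes_fps_only(self):
        gts = GroundTruthSet({"a": [Box(0, 0, 10, 10)]})
        perfect = DetectionSet({"a": [Box(0, 0, 10, 10, 0.9)]})
        with_ghost = DetectionSet(
            {"a": [Box(0, 0, 10, 10, 0.9)], "b": [Box(0, 0, 10, 10, 0.95)]}
        )
        assert map50(with_ghost, gts) < map50(perfect, gts)

    def test_synthetic_set_agrees_with_sweep_oracle(
        self, clean_dataset, clean_detections
    ):
        # cross-check of the full engine (pooled ranking, matching, AP)
        # against the independent threshold-sweep oracle on real pipeline
        # output; tolerance matches cross-tool comparisons
        _, _, gts = clean_dataset
        fast = map50(clean_detections, gts)
        confs, flags = [], []
        n_gt = 0
        for image_id in sorted(set(clean_detections.image_ids) | set(gts.image_ids)):
            labels = match_detections(
                clean_detections.boxes(image_id), gts.boxes(image_id), 0.5
            )
            confs.extend(labels.confidences)
            flags.extend(labels.tp)
            n_gt += labels.n_gt
        oracle = sweep_oracle_ap(confs, flags, n_gt)
        assert fast == pytest.approx(oracle, abs=1e-3)
        assert fast >= 0.9  # regression floor for the baseline detector


class TestCountingAgreement:
    def test_identical_vectors(self):
        result = counting_agreement([3, 5, 9, 2], [3, 5, 9, 2])
        assert result.pearson_r == pytest.approx(1.0)
        assert result.mae == 0.0
        assert result.n == 4

    def test_perfect_anticorrelation(self):
        result = counting_agreement([1, 2, 3], [3, 2, 1])
        assert result.pearson_r == pytest.approx(-1.0)

    def test_worked_case_against_closed_form(self):
        x = [10, 20, 30, 40]
        y = [12, 19, 33, 38]
        n = 4
        sx, sy = sum(x), sum(y)
        sxx = sum(v * v for v in x)
        syy = sum(v * v for v in y)
        sxy = sum(a * b for a, b in zip(x, y))
        expected = (n * sxy - sx * sy) / math.sqrt(
            (n * sxx - sx**2) * (n * syy - sy**2)
        )
        result = counting_agreement(x, y)
        assert result.pearson_r == pytest.approx(expected, abs=1e-12)
        assert result.mae == pytest.approx((2 + 1 + 3 + 2) / 4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            counting_agreement([5, 5, 5], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            counting_agreement([1, 2, 3], [1, 2])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            counting_agreement([1, 2], [1, 2])
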