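"""Metrics against an independent brute-force implementation.

The oracle below recomputes every quantity from first principles with
explicit python loops over classes and direct boolean masking — no
shared code with the package implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xaimri.metrics import (
    ConfusionCounts,
    accuracy,
    confusion_counts,
    dice_coefficient,
    mean_iou,
    metrics_report,
    precision,
    sensitivity,
    specificity,
)


def brute_force_report(pred, truth, n_classes):
    """Independent oracle: direct set arithmetic per class."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    n = pred.size
    tp = fp = fn = tn = 0
    per_class_iou = []
    inter_total = 0
    for c in range(n_classes):
        a = pred == c
        b = truth == c
        tp_c = int(np.sum(a & b))
        fp_c = int(np.sum(a & ~b))
        fn_c = int(np.sum(~a & b))
        tn_c = int(np.sum(~a & ~b))
        tp += tp_c
        fp += fp_c
        fn += fn_c
        tn += tn_c
        union = tp_c + fp_c + fn_c
        per_class_iou.append(1.0 if union == 0 else tp_c / union)
        inter_total += tp_c
    acc = float(np.mean(pred == truth))
    miou = float(np.mean(per_class_iou))
    # global one-hot Dice: sum of per-class intersections over total mass
    dice = 2.0 * inter_total / (2.0 * n)
    prec = tp / (tp + fp)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return acc, miou, dice, prec, sens, spec, per_class_iou


class TestConfusionCounts:
    def test_hand_tally_on_3x3_grid(self):
        pred = np.array([[0, 0, 1], [1, 1, 0], [0, 1, 1]])
        truth = np.array([[0, 1, 1], [1, 0, 0], [0, 0, 1]])
        c = confusion_counts(pred, truth, 2)
        # class 1: pred {1}: 5 cells, truth {1}: 4 cells, overlap positions (0,2),(1,0),(2,2)
        assert c.tp[1] == 3 and c.fp[1] == 2 and c.fn[1] == 1 and c.tn[1] == 3
        for cls in range(2):
            assert c.tp[cls] + c.fp[cls] + c.fn[cls] + c.tn[cls] == 9

    def test_perfect_prediction_has_no_errors(self, rng):
        y = rng.integers(0, 4, size=(6, 6, 6))
        c = confusion_counts(y, y, 4)
        assert np.all(c.fp == 0) and np.all(c.fn == 0)

    def test_shape_mismatch_and_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)), 2)
        with pytest.raises(ValueError, match="out-of-range"):
            confusion_counts(np.array([0, 5]), np.array([0, 1]), 4)


class TestScalarMetrics:
    def test_accuracy_from_binary_confusion_counts(self):
        # binary problem with TP=2, TN=5, FP=1, FN=2 -> accuracy 0.7;
        # in two-class one-vs-rest form the background row mirrors it
        c = ConfusionCounts(
            tp=np.array([5, 2]), fp=np.array([2, 1]), fn=np.array([1, 2]),
            tn=np.array([2, 5]), n_voxels=10,
        )
        assert accuracy(c) == pytest.approx(0.7)

    def test_precision_sensitivity_arithmetic(self):
        c = ConfusionCounts(
            tp=np.array([2]), fp=np.array([2]), fn=np.array([6]), tn=np.array([0]),
            n_voxels=10,
        )
        assert precision(c) == pytest.approx(0.5)
        assert sensitivity(c) == pytest.approx(0.25)

    def test_zero_denominator_yields_nan_not_zero(self):
        c = ConfusionCounts(
            tp=np.array([0]), fp=np.array([0]), fn=np.array([4]), tn=np.array([6]),
            n_voxels=10,
        )
        assert np.isnan(precision(c))
        assert specificity(c) == pytest.approx(1.0)

    def test_accuracy_equals_match_fraction_on_random_pairs(self, rng):
        for _ in range(100):
            pred = rng.integers(0, 4, size=(8, 8, 8))
            truth = rng.integers(0, 4, size=(8, 8, 8))
            c = confusion_counts(pred, truth, 4)
            assert accuracy(c) == pytest.approx(float((pred == truth).mean()), abs=1e-12)


class TestOverlapMetrics:
    def test_iou_direct_count(self):
        # A and B are 4-voxel sets overlapping in 2 voxels -> IoU 2/6
        pred = np.zeros((4, 4, 1), dtype=int)
        truth = np.zeros((4, 4, 1), dtype=int)
        pred[0, 0:4] = 1
        truth[0, 2:4] = 1
        truth[1, 0:2] = 1
        iou = mean_iou(pred, truth, 2)
        fg = 2 / 6
        bg = 10 / 14
        assert iou == pytest.approx((fg + bg) / 2)

    def test_mean_iou_of_constructed_per_class_values(self):
        pred = np.array([0, 0, 0, 0, 1, 1, 1, 0, 1, 1])
        truth = np.array([0, 0, 0, 1, 0, 1, 0, 1, 0, 0])
        from xaimri.metrics import per_class_iou

        iou, _ = per_class_iou(pred, truth, 2)
        assert iou[0] == pytest.approx(3 / 9)

    def test_dice_direct_count(self):
        pred = np.zeros((4, 4, 1), dtype=int)
        truth = np.zeros((4, 4, 1), dtype=int)
        pred[0, 0:4] = 1
        truth[0, 2:4] = 1
        truth[1, 0:2] = 1
        per_class = dice_coefficient(pred, truth, 2, mode="per_class")
        assert per_class[1] == pytest.approx(2 * 2 / (4 + 4))

    def test_identical_volumes_score_one(self, rng):
        y = rng.integers(0, 4, size=(6, 6, 6))
        assert mean_iou(y, y, 4) == 1.0
        assert dice_coefficient(y, y, 4) == 1.0

    def test_disjoint_masks_have_zero_foreground_dice(self):
        pred = np.array([1, 1, 0, 0])
        truth = np.array([0, 0, 1, 1])
        assert dice_coefficient(pred, truth, 2, mode="per_class")[1] == 0.0

    def test_soft_dice_accepts_probability_volume(self, rng):
        truth = rng.integers(0, 3, size=(4, 4, 4))
        onehot = np.moveaxis(np.eye(3)[truth], -1, 0)
        assert dice_coefficient(onehot, truth, 3) == pytest.approx(1.0)

    def test_empty_union_class_conventions(self):
        pred = np.zeros((3, 3, 3), dtype=int)
        truth = np.zeros((3, 3, 3), dtype=int)
        assert mean_iou(pred, truth, 4) == 1.0  # absent classes count as 1
        assert mean_iou(pred, truth, 4, empty_union="skip") == 1.0  # only class 0 kept


class TestReport:
    def test_report_lists_the_six_canonical_metrics(self, rng):
        y = rng.integers(0, 4, size=(5, 5, 5))
        rep = metrics_report(y, y, 4)
        assert list(rep.to_dict())[:6] == [
            "accuracy", "mean_iou", "dice_coef", "precision", "sensitivity", "specificity",
        ]
        for name in rep.METRIC_NAMES:
            assert getattr(rep, name) == pytest.approx(1.0)

    def test_report_matches_brute_force_oracle_on_random_pairs(self, rng):
        for _ in range(50):
            n_classes = int(rng.integers(2, 5))
            pred = rng.integers(0, n_classes, size=(16, 16, 16))
            truth = rng.integers(0, n_classes, size=(16, 16, 16))
            rep = metrics_report(pred, truth, n_classes)
            acc, miou, dice, prec, sens, spec, pci = brute_force_report(pred, truth, n_classes)
            assert rep.accuracy == pytest.approx(acc, abs=1e-12)
            assert rep.mean_iou == pytest.approx(miou, abs=1e-12)
            assert rep.dice_coef == pytest.approx(dice, abs=1e-12)
            assert rep.precision == pytest.approx(prec, abs=1e-12)
            assert rep.sensitivity == pytest.approx(sens, abs=1e-12)
            assert rep.specificity == pytest.approx(spec, abs=1e-12)
            assert rep.per_class_iou == pytest.approx(pci, abs=1e-12)

    def test_f1_identity_binary_micro_counts(self, rng):
        # micro-aggregated Dice equals the precision/sensitivity harmonic mean
        for _ in range(20):
            pred = rng.integers(0, 2, size=(10, 10))
            truth = rng.integers(0, 2, size=(10, 10))
            c = confusion_counts(pred, truth, 2)
            p, s = precision(c), sensitivity(c)
            micro_dice = 2 * c.micro_tp / (2 * c.micro_tp + c.micro_fp + c.micro_fn)
            assert micro_dice == pytest.approx(2 * p * s / (p + s), abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 5))
    def test_all_metrics_within_unit_interval(self, seed, n_classes):
        r = np.random.default_rng(seed)
        pred = r.integers(0, n_classes, size=(6, 6, 6))
        truth = r.integers(0, n_classes, size=(6, 6, 6))
        rep = metrics_report(pred, truth, n_classes)
        for name in rep.METRIC_NAMES:
            v = getattr(rep, name)
            assert np.isnan(v) or 0.0 <= v <= 1.0

    def test_mean_iou_invariant_under_consistent_relabeling(self, rng):
        pred = rng.integers(0, 4, size=(8, 8, 8))
        truth = rng.integers(0, 4, size=(8, 8, 8))
        perm = rng.permutation(4)
        assert mean_iou(pred, truth, 4) == pytest.approx(
            mean_iou(perm[pred], perm[truth], 4), abs=1e-12
        )
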