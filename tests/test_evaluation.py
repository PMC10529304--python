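"""Voxel-wise segmentation metrics, component matching and aggregation."""

import numpy as np
import pytest

from oracles import confusion_loop
from specimenseg.evaluation import (
    ConfusionCounts,
    aggregate,
    aggregate_metrics,
    class_metrics,
    confusion,
    evaluate,
    match_components,
)
from specimenseg.grid import LabelMask


def _mask(arr):
    return LabelMask(np.asarray(arr, dtype=np.int32), 1.0, 0.0)


class TestConfusion:
    def test_perfect_prediction(self):
        truth = np.zeros((5, 5, 4), bool)
        truth[1:3, 1:3, 1:3] = True
        c = confusion(truth, truth)
        n = int(truth.sum())
        assert (c.tp, c.tn, c.fp, c.fn) == (n, truth.size - n, 0, 0)

    def test_worked_example_metrics(self):
        """tp=8, fp=2, fn=2, tn=88 gives P=R=dice=0.8, J=2/3, acc=0.96."""
        m = class_metrics(ConfusionCounts(tp=8, tn=88, fp=2, fn=2))
        assert m["precision"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(0.8)
        assert m["dice"] == pytest.approx(0.8)
        assert m["jaccard"] == pytest.approx(2 / 3, abs=1e-4)
        assert m["accuracy"] == pytest.approx(0.96)

    def test_agrees_with_voxel_loop(self, rng):
        pred = rng.random((15, 15, 15)) < 0.3
        truth = rng.random((15, 15, 15)) < 0.3
        c = confusion(pred, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == confusion_loop(pred, truth)

    def test_agrees_with_sklearn(self, rng):
        """Independent cross-check against sklearn's metric implementations."""
        from sklearn.metrics import accuracy_score, f1_score, jaccard_score, precision_score, recall_score

        pred = (rng.random((12, 12, 12)) < 0.4).ravel()
        truth = (rng.random((12, 12, 12)) < 0.4).ravel()
        m = class_metrics(confusion(pred.reshape(12, 12, 12), truth.reshape(12, 12, 12)))
        assert m["precision"] == pytest.approx(precision_score(truth, pred))
        assert m["recall"] == pytest.approx(recall_score(truth, pred))
        assert m["dice"] == pytest.approx(f1_score(truth, pred))
        assert m["jaccard"] == pytest.approx(jaccard_score(truth, pred))
        assert m["accuracy"] == pytest.approx(accuracy_score(truth, pred))

    def test_counts_must_be_non_negative(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestClassMetrics:
    def test_dice_identities_hold_exactly(self, rng):
        for _ in range(20):
            tp, fp, fn = (int(v) for v in rng.integers(1, 1000, 3))
            m = class_metrics(ConfusionCounts(tp=tp, tn=10, fp=fp, fn=fn))
            p, r, j = m["precision"], m["recall"], m["jaccard"]
            assert m["dice"] == pytest.approx(2 * p * r / (p + r), abs=1e-12)
            assert m["dice"] == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_undefined_quotients_are_absent_not_zero(self):
        m = class_metrics(ConfusionCounts(tp=0, tn=100, fp=0, fn=0))
        assert np.isnan(m["precision"]) and np.isnan(m["recall"]) and np.isnan(m["dice"])
        assert m["accuracy"] == 1.0

    @pytest.mark.parametrize(
        "p,r,printed_dice",
        [(0.98, 0.78, 0.87), (0.98, 0.84, 0.90), (0.95, 0.82, 0.88),
         (0.99, 0.72, 0.83), (0.99, 0.64, 0.78), (1.00, 0.72, 0.84)],
    )
    def test_dice_from_precision_recall_rows(self, p, r, printed_dice):
        """Reported per-specimen P/R pairs reproduce their Dice at 2 decimals."""
        assert round(2 * p * r / (p + r), 2) == printed_dice

    @pytest.mark.parametrize(
        "j,printed_dice",
        [(0.77, 0.87), (0.82, 0.90), (0.79, 0.88), (0.71, 0.83), (0.64, 0.78), (0.72, 0.84)],
    )
    def test_dice_from_jaccard_rows(self, j, printed_dice):
        assert round(2 * j / (1 + j), 2) == printed_dice


class TestAggregate:
    def test_macro_is_unweighted_mean(self):
        rows = [{"precision": p} for p in (0.98, 0.98, 0.95)]
        assert round(aggregate_metrics(rows, mode="macro")["precision"], 2) == 0.97

    def test_macro_recall_right_side_rows(self):
        rows = [{"recall": r} for r in (0.72, 0.64, 0.72)]
        assert round(aggregate_metrics(rows, mode="macro")["recall"], 2) == 0.69

    def test_equal_supports_weighted_equals_macro(self):
        counts = [
            ConfusionCounts(tp=80, tn=800, fp=10, fn=20),
            ConfusionCounts(tp=60, tn=820, fp=30, fn=40),
        ]
        # equal truth supports (tp + fn = 100 each)
        macro = aggregate(counts, "macro")
        weighted = aggregate(counts, "weighted")
        for name in macro:
            assert macro[name] == pytest.approx(weighted[name], abs=1e-12)

    def test_micro_pools_counts(self):
        counts = [
            ConfusionCounts(tp=8, tn=88, fp=2, fn=2),
            ConfusionCounts(tp=4, tn=90, fp=4, fn=2),
        ]
        micro = aggregate(counts, "micro")
        pooled = class_metrics(ConfusionCounts(tp=12, tn=178, fp=6, fn=4))
        assert micro == pooled

    def test_zero_classes_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], "macro")


class TestMatchComponents:
    def test_identity_mapping(self):
        labels = np.zeros((6, 6, 6), dtype=np.int32)
        labels[0:2, 0:2, 0:2] = 1
        labels[4:6, 4:6, 4:6] = 2
        m = _mask(labels)
        assert match_components(m, m) == {1: 1, 2: 2}

    def test_maximal_overlap_wins(self):
        truth = np.zeros((10, 4, 4), dtype=np.int32)
        truth[0:4, :2, :2] = 1  # overlap 30 voxels below
        truth[6:9, :2, :2] = 2  # overlap 10 voxels below
        pred = np.zeros((10, 4, 4), dtype=np.int32)
        pred[0:4, :2, :2] = 7
        pred[6:7, :2, :2] = 7  # same predicted blob id spans both
        assert match_components(_mask(pred), _mask(truth)) == {7: 1}

    def test_disjoint_component_maps_to_none(self):
        truth = np.zeros((6, 6, 6), dtype=np.int32)
        truth[0:2, 0:2, 0:2] = 1
        pred = np.zeros((6, 6, 6), dtype=np.int32)
        pred[4:6, 4:6, 4:6] = 1
        assert match_components(_mask(pred), _mask(truth)) == {1: None}


class TestEvaluate:
    def test_perfect_prediction_all_ones(self):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[1:3, 1:3, 1:3] = 1
        labels[5:7, 5:7, 5:7] = 2
        report = evaluate(_mask(labels), _mask(labels))
        frame = report.to_frame()
        for name in ("precision", "recall", "dice", "jaccard", "accuracy"):
            assert np.allclose(frame[name], 1.0)

    def test_dice_jaccard_identity_rowwise(self, default_segmentation, default_phantom):
        labeled, _ = default_segmentation
        _, _, truth, _ = default_phantom
        frame = evaluate(labeled, truth).to_frame()
        d, j = frame["dice"].to_numpy(), frame["jaccard"].to_numpy()
        assert np.allclose(d, 2 * j / (1 + j), atol=1e-12)

    def test_dice_is_symmetric(self, rng):
        a = (rng.random((10, 10, 10)) < 0.3).astype(np.int32)
        b = (rng.random((10, 10, 10)) < 0.3).astype(np.int32)
        d_ab = class_metrics(confusion(a, b))["dice"]
        d_ba = class_metrics(confusion(b, a))["dice"]
        assert d_ab == pytest.approx(d_ba, abs=1e-12)

    def test_unmatched_components_count_as_micro_false_positives(self):
        truth = np.zeros((10, 10, 10), dtype=np.int32)
        truth[0:3, 0:3, 0:3] = 1
        pred = truth.copy()
        pred[7:9, 7:9, 7:9] = 2  # spurious disjoint blob
        report = evaluate(_mask(pred), _mask(truth))
        assert report.unmatched_fp == 8
        assert report.aggregate("micro")["precision"] < 1.0
        assert report.metrics(1)["precision"] == 1.0  # per-class counts untouched

    def test_accuracy_exceeds_dice_under_class_imbalance(self, default_segmentation, default_phantom):
        """Tiny targets in a large field of view inflate accuracy above Dice."""
        labeled, _ = default_segmentation
        _, _, truth, _ = default_phantom
        report = evaluate(labeled, truth)
        micro = report.aggregate("micro")
        assert micro["accuracy"] > micro["dice"] or micro["dice"] == 1.0

    def test_geometry_mismatch_rejected(self):
        a = _mask(np.ones((4, 4, 4), dtype=np.int32))
        b = LabelMask(np.ones((4, 4, 4), dtype=np.int32), 2.0, 0.0)
        with pytest.raises(ValueError, match="geometries differ"):
            evaluate(a, b)

    def test_empty_truth_rejected(self):
        empty = _mask(np.zeros((4, 4, 4), dtype=np.int32))
        with pytest.raises(ValueError, match="no labeled nodes"):
            evaluate(empty, empty)
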