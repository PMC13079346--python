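"""Evaluation metrics against hand counts and an established reference."""

import numpy as np
import pytest
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    jaccard_score,
    precision_score,
    recall_score,
)

from maefew.metrics import (
    classification_report,
    confusion,
    dice_iou,
    multiclass_dice_iou,
    stability,
)

RNG = np.random.default_rng(7)


class TestConfusion:
    def test_hand_counts_three_classes(self):
        counts = confusion([0, 0, 1, 2], [0, 1, 1, 2], K=3)
        assert counts.tp.tolist() == [1, 1, 1]
        assert counts.fp.tolist() == [0, 1, 0]
        assert counts.fn.tolist() == [1, 0, 0]

    def test_perfect_predictions(self):
        y = RNG.integers(0, 4, size=50)
        counts = confusion(y, y, K=4)
        assert np.all(counts.fp == 0) and np.all(counts.fn == 0)

    def test_tp_sum_is_correct_count(self):
        t = RNG.integers(0, 3, size=100)
        p = RNG.integers(0, 3, size=100)
        counts = confusion(t, p, K=3)
        assert counts.tp.sum() == np.sum(t == p)

    def test_errors(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0], K=2)
        with pytest.raises(ValueError):
            confusion([0, 5], [0, 1], K=2)


class TestClassificationReport:
    def test_toy_macro_f1(self):
        counts = confusion([0, 0, 1, 2], [0, 1, 1, 2], K=3)
        report = classification_report(counts)
        assert report.per_class_f1 == pytest.approx([2 / 3, 2 / 3, 1.0])
        assert report.f1_macro == pytest.approx(7 / 9)

    def test_micro_f1_equals_accuracy(self):
        t = RNG.integers(0, 5, size=200)
        p = RNG.integers(0, 5, size=200)
        report = classification_report(confusion(t, p, K=5))
        assert report.f1_micro == pytest.approx(report.accuracy, abs=1e-12)

    def test_balanced_classes_weighted_equals_macro(self):
        t = np.repeat([0, 1, 2], 30)
        p = RNG.integers(0, 3, size=90)
        report = classification_report(confusion(t, p, K=3))
        assert report.f1_weighted == pytest.approx(report.f1_macro, abs=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_agreement_with_sklearn_on_random_vectors(self, trial):
        rng = np.random.default_rng(trial)
        t = rng.integers(0, 6, size=1000)
        p = rng.integers(0, 6, size=1000)
        report = classification_report(confusion(t, p, K=6))
        assert report.accuracy == pytest.approx(accuracy_score(t, p), abs=1e-9)
        assert report.precision == pytest.approx(
            precision_score(t, p, average="micro"), abs=1e-9)
        assert report.recall == pytest.approx(
            recall_score(t, p, average="micro"), abs=1e-9)
        assert report.f1_micro == pytest.approx(
            f1_score(t, p, average="micro"), abs=1e-9)
        assert report.f1_macro == pytest.approx(
            f1_score(t, p, average="macro"), abs=1e-9)
        assert report.f1_weighted == pytest.approx(
            f1_score(t, p, average="weighted"), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_report(confusion([], [], K=2))


class TestDiceIoU:
    def test_identical_nonempty_masks(self):
        m = RNG.random((16, 16)) > 0.5
        assert dice_iou(m, m) == (1.0, 1.0)

    def test_hand_values(self):
        pred = np.zeros(24, dtype=bool)
        truth = np.zeros(24, dtype=bool)
        pred[:4] = True          # |P| = 4
        truth[2:8] = True        # |G| = 6, intersection = 2
        d, i = dice_iou(pred, truth)
        assert d == pytest.approx(0.4)
        assert i == pytest.approx(0.25)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), dtype=bool)
        assert dice_iou(z, z) == (1.0, 1.0)

    @pytest.mark.parametrize("trial", range(5))
    def test_algebraic_identity_and_sklearn(self, trial):
        rng = np.random.default_rng(trial)
        p = rng.random((12, 12)) > 0.4
        g = rng.random((12, 12)) > 0.6
        d, i = dice_iou(p, g)
        assert 0 <= i <= d <= 1
        assert i == pytest.approx(d / (2 - d), abs=1e-9)
        assert i == pytest.approx(
            jaccard_score(g.ravel(), p.ravel()), abs=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_iou(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMulticlass:
    def test_perfect_segmentation(self):
        labels = RNG.integers(0, 4, size=(10, 10))
        report = multiclass_dice_iou(labels, labels, K=4)
        assert report.per_class_dice == [1.0] * 4
        assert report.mean_dice == 1.0

    def test_absent_class_scores_one_with_warning(self):
        labels = np.zeros((6, 6), dtype=int)
        with pytest.warns(UserWarning, match="absent"):
            report = multiclass_dice_iou(labels, labels, K=3)
        assert report.per_class_dice[2] == 1.0

    def test_mean_is_arithmetic_over_foreground(self):
        t = RNG.integers(0, 3, size=(20, 20))
        p = RNG.integers(0, 3, size=(20, 20))
        report = multiclass_dice_iou(p, t, K=3)
        assert report.mean_dice == pytest.approx(
            np.mean(report.per_class_dice[1:]), abs=1e-9)
        with_bg = multiclass_dice_iou(p, t, K=3, include_background=True)
        assert with_bg.mean_dice == pytest.approx(
            np.mean(report.per_class_dice), abs=1e-9)


class TestStability:
    def test_constant_series(self):
        s = stability([5.0, 5.0, 5.0])
        assert s.mean == 5.0 and s.std == 0.0

    def test_population_not_sample_std(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        s = stability(vals)
        assert s.std == pytest.approx(np.std(vals, ddof=0))
        assert s.std < np.std(vals, ddof=1)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            stability([1.0])
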