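import numpy as np
import pandas as pd
import pytest

from radsig.models import (
    ModelSpec,
    accuracy_vs_feature_count,
    confusion_metrics,
    cross_validate,
    evaluate_predictors,
    saturation_point,
)
from radsig.phantoms import generate_tabular_cohort


class TestConfusionMetrics:
    def test_binary_arithmetic(self):
        # TP=8 FN=2 / FP=3 TN=7 with class 0 positive
        cm = np.array([[8, 2], [3, 7]])
        m = confusion_metrics(cm)
        assert m["sensitivity"] == pytest.approx(80.0)
        assert m["specificity"] == pytest.approx(70.0)
        assert m["precision"] == pytest.approx(72.7, abs=0.05)
        assert m["npv"] == pytest.approx(77.8, abs=0.05)
        assert m["accuracy"] == pytest.approx(75.0)
        assert m["f_score"] == pytest.approx(76.2, abs=0.05)

    def test_three_class_macro_average(self):
        cm = np.diag([5, 5, 5])
        m = confusion_metrics(cm)
        assert all(v == pytest.approx(100.0) for v in m.values())

    def test_metrics_bounded(self):
        rng = np.random.default_rng(0)
        cm = rng.integers(0, 20, (3, 3))
        m = confusion_metrics(cm)
        assert all(0.0 <= v <= 100.0 for v in m.values())


class TestCrossValidate:
    def test_separable_data_perfect_accuracy(self):
        x, y = generate_tabular_cohort(40, n_signal=4, effect_size=6.0, seed=0)
        for kind in ("cart", "svm_rbf", "gaussian_nb"):
            rep = cross_validate(x, y, ModelSpec(kind=kind), folds=10, seed=1)
            assert rep.accuracy == 100.0

    def test_permuted_labels_near_chance(self):
        x, y = generate_tabular_cohort(60, n_signal=4, effect_size=3.0, seed=1)
        accs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            yp = pd.Series(
                rng.permutation(y.to_numpy()), index=y.index, name="label"
            )
            rep = cross_validate(x, yp, ModelSpec(), folds=10, seed=seed)
            accs.append(rep.accuracy)
        assert 30.0 < np.mean(accs) < 70.0  # binary chance ~ 50%

    def test_deterministic_given_seed(self):
        x, y = generate_tabular_cohort(30, seed=2, effect_size=1.0)
        a = cross_validate(x, y, ModelSpec(kind="svm_rbf"), folds=5, seed=3)
        b = cross_validate(x, y, ModelSpec(kind="svm_rbf"), folds=5, seed=3)
        assert np.array_equal(a.confusion, b.confusion)
        assert a.metrics() == b.metrics()

    def test_confusion_rows_sum_to_class_counts(self):
        x, y = generate_tabular_cohort(45, n_classes=3, seed=4, effect_size=1.5)
        rep = cross_validate(x, y, ModelSpec(), folds=5, seed=0)
        counts = y.value_counts().sort_index()
        assert rep.confusion.sum() == len(y)
        for cls, row_sum in zip(rep.classes, rep.confusion.sum(axis=1)):
            assert row_sum == counts[cls]

    def test_small_class_reduces_folds(self):
        x, y = generate_tabular_cohort(12, seed=5)
        with pytest.warns(UserWarning):
            rep = cross_validate(x, y, ModelSpec(), folds=10, seed=0)
        assert rep.n_folds <= 6


class TestEvaluatePredictors:
    def test_identical_predictors_zero_improvement(self):
        x, y = generate_tabular_cohort(40, seed=6, effect_size=2.0)
        comp = evaluate_predictors(
            {"radsig": x, "other": x.copy()}, y, ModelSpec(), folds=5, seed=0
        )
        for metric in ("accuracy", "f_score"):
            assert comp.loc["other", f"improvement_{metric}"] == pytest.approx(0.0)

    def test_texture_signal_invisible_to_suv_mean(self):
        # planted signal features vs a pure-noise single-column comparator
        x, y = generate_tabular_cohort(
            50, n_features=6, n_signal=4, effect_size=3.0, seed=7
        )
        noise = x[["decoy_0"]].rename(columns={"decoy_0": "suv_mean"})
        comp = evaluate_predictors(
            {"radsig": x[[f"signal_{i}" for i in range(4)]], "suv_mean": noise},
            y, ModelSpec(), folds=10, seed=0,
        )
        assert comp.loc["suv_mean", "improvement_accuracy"] > 0


class TestAccuracyCurve:
    def test_curve_has_max_n_points(self):
        x, y = generate_tabular_cohort(30, n_features=8, seed=8)
        curve = accuracy_vs_feature_count(
            x, y, list(x.columns), max_n=6, folds=5, seed=0
        )
        assert len(curve) == 6
        assert set(curve.columns) == {"cart", "svm_rbf", "gaussian_nb"}

    def test_flat_at_chance_for_noise_labels(self):
        x, y = generate_tabular_cohort(
            60, n_features=8, effect_size=0.0, seed=9
        )
        curve = accuracy_vs_feature_count(
            x, y, list(x.columns), max_n=5, folds=5, seed=0
        )
        assert curve["gaussian_nb"].max() < 75.0

    def test_accuracy_nondecreasing_in_effect_size(self):
        means = []
        for eff in (0.0, 0.8, 1.6):
            accs = [
                cross_validate(
                    *generate_tabular_cohort(50, effect_size=eff, seed=s),
                    ModelSpec(), folds=10, seed=s,
                ).accuracy
                for s in range(3)
            ]
            means.append(np.mean(accs))
        assert means[0] - 5.0 <= means[1] <= means[2] + 5.0
        assert means[2] > means[0]

    def test_saturation_point_of_step_curve(self):
        curve = pd.Series([60, 80, 92, 95, 95.5, 95.4], index=range(1, 7))
        assert saturation_point(curve) == 4  # 95 >= 0.98 * 95.5
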