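"""Classifier contract, confusion matrices, metrics and fold aggregation."""

import numpy as np
import pandas as pd
import pytest

from actistrat import ClassifierSpec, aggregate_folds, confusion, fit_predict, metrics
from actistrat.constants import ACTIVITIES
from actistrat.exceptions import ConfigurationError, ContractError, UnknownLabelError
from actistrat.model_eval import grid_specs
from test_stratify import toy_features


class TestFitPredict:
    def test_one_nn_memorizes_training_rows(self):
        train = toy_features({"inactive": 20, "walking": 20}, seed=1)
        pred = fit_predict(ClassifierSpec("1nn"), train, train.iloc[:10])
        assert list(pred) == list(train["activity"].iloc[:10])

    def test_majority_baseline(self):
        train = toy_features({"inactive": 30, "walking": 5}, seed=2)
        test = toy_features({"driving": 8}, seed=3)
        pred = fit_predict(ClassifierSpec("majority"), train, test)
        assert set(pred) == {"inactive"}

    def test_gradient_boosting_separates_a_wide_margin(self):
        # Two classes split by f0 with a 5-sigma margin; a hand-rolled
        # threshold verifies separability before the learner is asked to.
        rng = np.random.default_rng(6)
        train = toy_features({"walking": 100, "driving": 100}, n_feature_cols=3, seed=6)
        shift = np.where(train["activity"] == "walking", 0.0, 10.0)
        train["f0"] = rng.normal(0, 1, len(train)) + shift
        threshold_pred = np.where(train["f0"] < 5.0, "walking", "driving")
        assert (threshold_pred == train["activity"]).all()
        pred = fit_predict(ClassifierSpec("xgboost", seed=0), train, train)
        assert (pred == train["activity"]).mean() == 1.0

    def test_deterministic_given_seed(self):
        train = toy_features({"inactive": 40, "walking": 40}, seed=4)
        test = toy_features({"inactive": 10, "walking": 10}, seed=5)
        a = fit_predict(ClassifierSpec("xgboost", seed=11), train, test)
        b = fit_predict(ClassifierSpec("xgboost", seed=11), train, test)
        assert list(a) == list(b)

    def test_unknown_learner_and_schema_mismatch(self):
        train = toy_features({"inactive": 12, "walking": 12})
        with pytest.raises(ConfigurationError):
            fit_predict(ClassifierSpec("nonsense"), train, train)
        with pytest.raises(ContractError):
            fit_predict(ClassifierSpec("majority"), train,
                        train.drop(columns=["f0"]))

    def test_grid_hook_is_a_cartesian_product(self):
        specs = grid_specs("xgboost", {"max_depth": [2, 4, 6], "n_estimators": [10, 20]})
        assert len(specs) == 6
        assert len({tuple(sorted(s.hyperparameters.items())) for s in specs}) == 6


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        labels = list(ACTIVITIES) * 3
        cm = confusion(labels, labels)
        assert np.trace(cm.to_numpy()) == 12
        assert cm.to_numpy().sum() == 12

    def test_everything_predicted_inactive_fills_first_column(self):
        cm = confusion(list(ACTIVITIES), ["inactive"] * 4)
        np.testing.assert_array_equal(cm["inactive"], [1, 1, 1, 1])
        assert cm.drop(columns="inactive").to_numpy().sum() == 0

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(9)
        actual = rng.choice(ACTIVITIES, 1000)
        predicted = rng.choice(ACTIVITIES, 1000)
        cm = confusion(actual, predicted)
        for a in ACTIVITIES:
            for p in ACTIVITIES:
                expected = sum(1 for x, y in zip(actual, predicted) if x == a and y == p)
                assert cm.loc[a, p] == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(UnknownLabelError):
            confusion(["inactive"], ["sprinting"])


class TestMetrics:
    def test_diagonal_matrix_gives_perfect_scores(self):
        cm = confusion(list(ACTIVITIES) * 5, list(ACTIVITIES) * 5)
        rep = metrics(cm)
        assert rep.overall_accuracy == 1.0
        assert (rep.per_class[["precision", "recall", "f_score"]] == 1.0).all().all()

    def test_balanced_errors_give_equal_precision_recall_f(self):
        # walking: TP=8, FP=2, FN=2 → precision = recall = F = 0.8
        actual = ["walking"] * 10 + ["driving"] * 10
        predicted = ["walking"] * 8 + ["driving"] * 2 + ["walking"] * 2 + ["driving"] * 8
        rep = metrics(confusion(actual, predicted))
        row = rep.per_class.loc["walking"]
        assert row["precision"] == pytest.approx(0.8)
        assert row["recall"] == pytest.approx(0.8)
        assert row["f_score"] == pytest.approx(0.8)

    def test_matches_one_vs_rest_brute_force(self):
        rng = np.random.default_rng(13)
        actual = rng.choice(ACTIVITIES, 500)
        predicted = rng.choice(ACTIVITIES, 500)
        rep = metrics(confusion(actual, predicted))
        for cls in ACTIVITIES:
            tp = sum(1 for a, p in zip(actual, predicted) if a == cls and p == cls)
            fp = sum(1 for a, p in zip(actual, predicted) if a != cls and p == cls)
            fn = sum(1 for a, p in zip(actual, predicted) if a == cls and p != cls)
            tn = 500 - tp - fp - fn
            row = rep.per_class.loc[cls]
            assert row["precision"] == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
            assert row["recall"] == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
            assert row["ovr_accuracy"] == pytest.approx((tp + tn) / 500)
        assert rep.overall_accuracy == pytest.approx(
            sum(1 for a, p in zip(actual, predicted) if a == p) / 500)

    def test_zero_denominators_reported_as_zero_and_flagged(self):
        # nothing predicted or actually "driving"
        rep = metrics(confusion(["inactive"] * 5, ["inactive"] * 5))
        assert rep.per_class.loc["driving", "precision"] == 0.0
        assert ("driving", "precision") in rep.undefined
        assert ("driving", "recall") in rep.undefined

    def test_invariant_under_class_permutation(self):
        rng = np.random.default_rng(21)
        actual = rng.choice(ACTIVITIES, 300)
        predicted = rng.choice(ACTIVITIES, 300)
        rep = metrics(confusion(actual, predicted))
        swap = {"inactive": "driving", "driving": "inactive",
                "active": "walking", "walking": "active"}
        rep2 = metrics(confusion([swap[a] for a in actual], [swap[p] for p in predicted]))
        assert rep2.overall_accuracy == pytest.approx(rep.overall_accuracy)
        for cls in ACTIVITIES:
            pd.testing.assert_series_equal(rep.per_class.loc[cls],
                                           rep2.per_class.loc[swap[cls]],
                                           check_names=False)


class TestAggregation:
    @staticmethod
    def _report(accuracy):
        cm = confusion(["inactive", "walking"], ["inactive", "walking"])
        rep = metrics(cm)
        rep.overall_accuracy = accuracy
        return rep

    def test_two_point_mean_and_sd(self):
        out = aggregate_folds([self._report(0.8), self._report(1.0)])
        assert out.loc["overall_accuracy", "mean"] == pytest.approx(0.9)
        assert out.loc["overall_accuracy", "sd"] == pytest.approx(0.1414, abs=1e-4)

    def test_single_fold_sd_is_zero(self):
        out = aggregate_folds([self._report(0.7)])
        assert out.loc["overall_accuracy", "sd"] == 0.0

    def test_matches_brute_force_formulas(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.5, 1.0, 10)
        out = aggregate_folds([self._report(v) for v in vals])
        mean = sum(vals) / 10
        sd = (sum((v - mean) ** 2 for v in vals) / 9) ** 0.5
        assert out.loc["overall_accuracy", "mean"] == pytest.approx(mean)
        assert out.loc["overall_accuracy", "sd"] == pytest.approx(sd)
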