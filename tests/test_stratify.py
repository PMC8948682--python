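"""Fold construction for the three information-sharing levels."""

import numpy as np
import pandas as pd
import pytest

from actistrat import (
    ClassifierSpec,
    build_loso_bands,
    loso_stratify,
    random_stratify,
    run_cross_validation,
    tripwise_stratify,
)
from actistrat.constants import ACTIVITIES
from actistrat.exceptions import BandingError, StratificationError
from actistrat.stratify import _coverage_table


def toy_features(class_counts, n_feature_cols=3, seed=0, trips_per_class=5):
    """A minimal feature table: counts per activity, windows spread over trips."""
    rng = np.random.default_rng(seed)
    rows = []
    for activity, n in class_counts.items():
        for i in range(n):
            trip = f"{activity[:2]}-{i % trips_per_class}"
            rows.append({
                "participant": f"p{i % 4:02d}",
                "trip": trip,
                "activity": activity,
                "window_index": i // trips_per_class,
                "synthetic": False,
            })
    table = pd.DataFrame(rows)
    feats = rng.normal(size=(len(table), n_feature_cols))
    for j in range(n_feature_cols):
        table[f"f{j}"] = feats[:, j]
    return table


class TestRandomStratify:
    def test_exact_division(self):
        table = toy_features({"inactive": 100})
        fa = random_stratify(table, n_folds=10, seed=1)
        counts = pd.Series(list(fa.assignment.values())).value_counts()
        assert sorted(counts) == [10] * 10

    def test_remainder_goes_to_tenth_fold(self):
        table = toy_features({"inactive": 103})
        fa = random_stratify(table, n_folds=10, seed=1)
        counts = pd.Series(list(fa.assignment.values())).value_counts().sort_index()
        assert list(counts[:9]) == [10] * 9
        assert counts[9] == 13

    def test_per_activity_counts_match_brute_force(self):
        table = toy_features({"inactive": 57, "active": 41, "walking": 33, "driving": 90})
        fa = random_stratify(table, n_folds=10, seed=3)
        folds = fa.row_folds(table)
        for activity in ACTIVITIES:
            n = (table["activity"] == activity).sum()
            tally = {}
            for fold, act in zip(folds, table["activity"]):
                if act == activity:
                    tally[fold] = tally.get(fold, 0) + 1
            for f in range(9):
                assert tally[f] == n // 10
            assert tally[9] == n - 9 * (n // 10)

    def test_class_smaller_than_folds_is_an_error(self):
        table = toy_features({"inactive": 100, "walking": 4})
        with pytest.raises(StratificationError, match="walking"):
            random_stratify(table, n_folds=10)


class TestTripwiseStratify:
    def test_even_split_of_trip_counts(self):
        table = toy_features({"driving": 73}, trips_per_class=73)
        fa = tripwise_stratify(table, n_folds=10, seed=2)
        per_fold = pd.Series(list(fa.assignment.values())).value_counts()
        assert sorted(per_fold) == [7] * 7 + [8] * 3

    def test_ten_trips_one_per_fold(self):
        table = toy_features({"walking": 10}, trips_per_class=10)
        fa = tripwise_stratify(table, n_folds=10, seed=2)
        assert sorted(fa.assignment.values()) == list(range(10))

    def test_fold_trip_counts_differ_by_at_most_one_per_activity(self, small_features):
        fa = tripwise_stratify(small_features, n_folds=10, seed=5)
        trips = small_features[["trip", "activity"]].drop_duplicates()
        for activity in ACTIVITIES:
            ids = trips.loc[trips["activity"] == activity, "trip"]
            folds = pd.Series([fa.assignment[t] for t in ids]).value_counts()
            counts = [folds.get(f, 0) for f in range(10)]
            assert max(counts) - min(counts) <= 1

    def test_windows_inherit_their_trips_fold(self, small_features):
        fa = tripwise_stratify(small_features, n_folds=10, seed=5)
        folds = fa.row_folds(small_features)
        per_trip = pd.DataFrame({"trip": small_features["trip"], "fold": folds})
        assert (per_trip.groupby("trip")["fold"].nunique() == 1).all()


def coverage_frame(rows):
    """rows: participant -> window count per activity (in fixed order)."""
    return pd.DataFrame(
        {a: [r[i] for r in rows.values()] for i, a in enumerate(ACTIVITIES)},
        index=list(rows),
    )


class TestLosoBands:
    def test_complete_participants_stay_singletons(self):
        cov = coverage_frame({f"p{i}": (5, 5, 5, 5) for i in range(6)})
        bands = build_loso_bands(cov)
        assert len(bands) == 6
        assert all(len(b.participants) == 1 for b in bands)

    def test_complementary_participants_are_merged(self):
        cov = coverage_frame({
            "p0": (4, 0, 0, 4),   # inactive + driving only
            "p1": (0, 4, 4, 0),   # active + walking only
            "p2": (3, 3, 3, 3),
            "p3": (3, 3, 3, 3),
        })
        bands = build_loso_bands(cov)
        merged = [b for b in bands if len(b.participants) > 1]
        assert len(merged) == 1
        assert merged[0].participants == ("p0", "p1")

    def test_participants_missing_activities_never_form_singletons(self):
        cov = coverage_frame({
            "p0": (666, 0, 0, 153),
            "p1": (159, 0, 675, 356),
            "p2": (20, 876, 1014, 602),
            "p3": (849, 868, 63, 260),
            "p4": (331, 487, 489, 3499),
            "p5": (0, 2008, 973, 0),
        })
        bands = build_loso_bands(cov)
        incomplete = {"p0", "p1", "p5"}
        for band in bands:
            if set(band.participants) & incomplete:
                assert len(band.participants) > 1
            assert all(v > 0 for v in band.window_counts.values())

    def test_activity_covered_by_single_participant_fails(self):
        cov = coverage_frame({
            "p0": (5, 5, 5, 5),
            "p1": (5, 5, 0, 5),
            "p2": (5, 5, 0, 5),
        })
        with pytest.raises(BandingError, match="walking"):
            build_loso_bands(cov)

    def test_every_band_covers_every_present_activity(self, small_features):
        bands = build_loso_bands(_coverage_table(small_features))
        present = set(small_features["activity"].unique())
        for band in bands:
            covered = {a for a, n in band.window_counts.items() if n > 0}
            assert present <= covered


@pytest.fixture(scope="module")
def cv_result(small_features):
    fa = tripwise_stratify(small_features, n_folds=5, seed=3)
    preds = run_cross_validation(small_features, fa,
                                 classifier=ClassifierSpec("majority"))
    return fa, preds


class TestCrossValidation:
    def test_every_window_predicted_exactly_once(self, small_features, cv_result):
        _, preds = cv_result
        assert sorted(preds.index) == sorted(small_features.index)

    def test_train_test_units_disjoint_per_fold(self, small_features, cv_result):
        fa, preds = cv_result
        folds = fa.row_folds(small_features)
        for f in sorted(set(folds)):
            test_trips = set(small_features.iloc[folds == f]["trip"])
            train_trips = set(small_features.iloc[folds != f]["trip"])
            assert not (test_trips & train_trips)

    def test_loso_participants_disjoint(self, small_features):
        fa = loso_stratify(small_features)
        preds = run_cross_validation(small_features, fa,
                                     classifier=ClassifierSpec("majority"))
        assert preds["fold"].nunique() == fa.n_folds
        folds = fa.row_folds(small_features)
        for f in sorted(set(folds)):
            test_p = set(small_features.iloc[folds == f]["participant"])
            train_p = set(small_features.iloc[folds != f]["participant"])
            assert not (test_p & train_p)

    def test_predictions_carry_metadata(self, cv_result):
        _, preds = cv_result
        assert {"participant", "trip", "activity", "window_index",
                "fold", "predicted"} <= set(preds.columns)
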