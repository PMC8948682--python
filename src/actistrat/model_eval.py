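"""Classifier registry, confusion matrices and evaluation metrics.

Learners are delegated to scikit-learn / xgboost behind a uniform
fit/predict contract keyed by name; this module owns only the contract,
seeding and defaults.  The default learner is gradient-boosted trees, which
gives a strong accuracy/compute trade-off on these tabular features.

Metrics follow the one-vs-rest reduction per class: precision
TP/(TP+FP), recall TP/(TP+FN), F-score as their harmonic mean, and a
per-class one-vs-rest accuracy (TP+TN)/total.  The overall multiclass
accuracy reported alongside is trace/total of the confusion matrix — the two
notions are computed and labelled distinctly.  Zero-denominator ratios are
reported as 0 and flagged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .constants import ACTIVITIES, METADATA_COLUMNS
from .exceptions import ConfigurationError, ContractError, UnknownLabelError

__all__ = [
    "ACTIVITIES", "ClassifierSpec", "MetricsReport", "fit_predict",
    "confusion", "metrics", "aggregate_folds", "grid_specs", "REGISTRY",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """A registered learner name, its hyperparameter overrides, and a seed."""

    name: str = "xgboost"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


def _xgboost(hp: dict, seed: int):
    from xgboost import XGBClassifier

    defaults = dict(n_estimators=60, max_depth=4, learning_rate=0.3,
                    tree_method="hist", n_jobs=1, random_state=seed)
    defaults.update(hp)
    return XGBClassifier(**defaults)


def _random_forest(hp: dict, seed: int):
    defaults = dict(n_estimators=100, n_jobs=1, random_state=seed)
    defaults.update(hp)
    return RandomForestClassifier(**defaults)


def _svm(hp: dict, seed: int):
    defaults = dict(kernel="rbf", gamma="scale", C=1.0, random_state=seed)
    defaults.update(hp)
    return make_pipeline(StandardScaler(), SVC(**defaults))


def _knn(hp: dict, seed: int):
    defaults = dict(n_neighbors=5)
    defaults.update(hp)
    return make_pipeline(StandardScaler(), KNeighborsClassifier(**defaults))


def _one_nn(hp: dict, seed: int):
    defaults = dict(n_neighbors=1)
    defaults.update(hp)
    return KNeighborsClassifier(**defaults)


def _naive_bayes(hp: dict, seed: int):
    return GaussianNB(**hp)


def _neural_network(hp: dict, seed: int):
    # Feed-forward net with package-chosen defaults (architecture is an
    # open choice; documented in the methods note).
    defaults = dict(hidden_layer_sizes=(64, 32), max_iter=300, random_state=seed)
    defaults.update(hp)
    return make_pipeline(StandardScaler(), MLPClassifier(**defaults))


def _majority(hp: dict, seed: int):
    return DummyClassifier(strategy="most_frequent")


REGISTRY = {
    "xgboost": _xgboost,
    "random_forest": _random_forest,
    "svm": _svm,
    "knn": _knn,
    "1nn": _one_nn,
    "naive_bayes": _naive_bayes,
    "neural_network": _neural_network,
    "majority": _majority,
}


def make_estimator(spec: ClassifierSpec):
    """Instantiate the learner a spec names."""
    try:
        factory = REGISTRY[spec.name]
    except KeyError:
        raise ConfigurationError(
            f"unknown learner {spec.name!r}; registered: {sorted(REGISTRY)}"
        ) from None
    return factory(dict(spec.hyperparameters), spec.seed)


def _split_features(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in table.columns if c not in METADATA_COLUMNS]
    if not cols:
        raise ContractError("table has no feature columns")
    return table[cols]


def fit_predict(spec: ClassifierSpec, train: pd.DataFrame, test: pd.DataFrame) -> np.ndarray:
    """Fit the named learner on a training table, predict test labels.

    Labels are encoded against the fixed activity order internally (several
    learners need integer classes); predictions come back as activity
    strings.  Deterministic for seedable learners given ``spec.seed``.
    """
    if len(train) == 0:
        raise ContractError("training table is empty")
    x_train = _split_features(train)
    x_test = _split_features(test)
    if list(x_train.columns) != list(x_test.columns):
        raise ContractError("train/test feature schemas differ")
    classes = sorted(train["activity"].unique(),
                     key=lambda a: ACTIVITIES.index(a) if a in ACTIVITIES else 99)
    code = {a: i for i, a in enumerate(classes)}
    y_train = train["activity"].map(code).to_numpy()
    est = make_estimator(spec)
    est.fit(x_train.to_numpy(dtype=float), y_train)
    pred = est.predict(x_test.to_numpy(dtype=float))
    return np.asarray([classes[int(i)] for i in pred])


def grid_specs(name: str, grid: dict[str, list], seed: int = 0) -> list[ClassifierSpec]:
    """Cartesian-product hyperparameter grid over one learner."""
    keys = sorted(grid)
    return [
        ClassifierSpec(name=name, hyperparameters=dict(zip(keys, values)), seed=seed)
        for values in itertools.product(*(grid[k] for k in keys))
    ]


def confusion(actual, predicted) -> pd.DataFrame:
    """4×4 confusion matrix; rows = actual, columns = predicted."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ContractError("actual and predicted must have equal length")
    bad = set(actual) | set(predicted)
    bad -= set(ACTIVITIES)
    if bad:
        raise UnknownLabelError(f"labels outside the activity alphabet: {sorted(bad)}")
    cm = _sk_confusion(actual, predicted, labels=list(ACTIVITIES))
    return pd.DataFrame(cm, index=list(ACTIVITIES), columns=list(ACTIVITIES))


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus overall multiclass accuracy."""

    per_class: pd.DataFrame  # index: class; columns: precision, recall, f_score, ovr_accuracy
    overall_accuracy: float
    undefined: list  # (class, metric) pairs where a denominator was zero


def metrics(cm: pd.DataFrame) -> MetricsReport:
    """Evaluation metrics from a confusion matrix (one-vs-rest per class)."""
    m = cm.to_numpy(dtype=float)
    total = m.sum()
    if total <= 0:
        raise ContractError("confusion matrix is empty")
    tp = np.diag(m)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    tn = total - tp - fp - fn
    undefined = []
    rows = {}
    for i, cls in enumerate(cm.index):
        prec_den = tp[i] + fp[i]
        rec_den = tp[i] + fn[i]
        precision = tp[i] / prec_den if prec_den > 0 else 0.0
        recall = tp[i] / rec_den if rec_den > 0 else 0.0
        if prec_den == 0:
            undefined.append((cls, "precision"))
        if rec_den == 0:
            undefined.append((cls, "recall"))
        if precision + recall > 0:
            f_score = 2.0 * precision * recall / (precision + recall)
        else:
            f_score = 0.0
            undefined.append((cls, "f_score"))
        rows[cls] = {
            "precision": precision,
            "recall": recall,
            "f_score": f_score,
            "ovr_accuracy": (tp[i] + tn[i]) / total,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    return MetricsReport(
        per_class=per_class,
        overall_accuracy=float(np.trace(m) / total),
        undefined=undefined,
    )


def aggregate_folds(reports: list[MetricsReport]) -> pd.DataFrame:
    """Mean and sample standard deviation per metric across folds.

    Returns a table with one row per metric (per-class metrics plus overall
    accuracy); SD uses denominator n−1 and is 0 for a single fold.
    """
    if not reports:
        raise ContractError("no fold reports to aggregate")
    records: dict[str, list[float]] = {}
    for rep in reports:
        records.setdefault("overall_accuracy", []).append(rep.overall_accuracy)
        for cls, row in rep.per_class.iterrows():
            for metric, value in row.items():
                records.setdefault(f"{cls}_{metric}", []).append(float(value))
    out = []
    for name, values in records.items():
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out.append({"metric": name, "mean": float(arr.mean()), "sd": sd,
                    "n_folds": int(arr.size)})
    return pd.DataFrame(out).set_index("metric")
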