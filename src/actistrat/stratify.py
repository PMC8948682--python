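"""Train/test stratification at three information-sharing levels.

* ``random``   — activity-stratified 10-fold split of individual windows;
  overlapping windows of one trip land in different folds, so train and
  test share window-level, trip-level and participant-level information.
* ``tripwise`` — whole trips are dealt to folds (per activity, trip counts
  spread evenly); only participant-level information is shared.
* ``loso``     — leave-one-subject-out over participant *bands*: because
  some participants skip activities, participants are greedily merged into
  bands whose held-out sets cover every activity; no information is shared.

The cross-validation driver fits one model per fold on the complement,
applies class balancing to the TRAINING side only (refusing to run if train
and test ids intersect — the leakage guard), and records test predictions
with trip and participant metadata so the voting smoother can run per trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balance import BalanceConfig, balance_table
from .constants import ACTIVITIES
from .exceptions import BandingError, ConfigurationError, LeakageError, StratificationError
from .model_eval import ClassifierSpec, fit_predict

logger = logging.getLogger(__name__)

SCHEMES = ("random", "tripwise", "loso")


@dataclass(frozen=True)
class FoldAssignment:
    """A partition of stratification units into folds.

    ``assignment`` maps a unit id to a fold index; the unit is a window row
    id (``random``), a trip id (``tripwise``) or a participant id
    (``loso``, fold = band index).
    """

    scheme: str
    n_folds: int
    assignment: dict = field(default_factory=dict)
    seed: int = 0

    def row_folds(self, features: pd.DataFrame) -> np.ndarray:
        """Fold index of every feature-table row under this assignment."""
        if self.scheme == "random":
            keys = features.index
        elif self.scheme == "tripwise":
            keys = features["trip"]
        elif self.scheme == "loso":
            keys = features["participant"]
        else:
            raise ConfigurationError(f"unknown scheme {self.scheme!r}")
        return np.asarray([self.assignment[k] for k in keys])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "unit_id": list(self.assignment),
            "scheme": self.scheme,
            "fold": list(self.assignment.values()),
        })


@dataclass(frozen=True)
class ParticipantBand:
    """A merged group of participants forming one leave-out unit."""

    band_id: int
    participants: tuple[str, ...]
    window_counts: dict  # activity -> held-out window count


def random_stratify(features: pd.DataFrame, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Deal windows of each activity into folds (seeded shuffle).

    The first ``n_folds − 1`` folds each receive ``floor(n / n_folds)``
    windows of every activity; the last fold absorbs the remainder.
    """
    rng = np.random.default_rng(seed)
    assignment: dict = {}
    for activity in ACTIVITIES:
        ids = features.index[features["activity"] == activity].to_numpy()
        if ids.size == 0:
            continue
        if ids.size < n_folds:
            raise StratificationError(
                f"activity {activity!r} has {ids.size} windows, fewer than "
                f"{n_folds} folds"
            )
        perm = rng.permutation(ids)
        base = ids.size // n_folds
        for f in range(n_folds - 1):
            for uid in perm[f * base: (f + 1) * base]:
                assignment[uid] = f
        for uid in perm[(n_folds - 1) * base:]:
            assignment[uid] = n_folds - 1
    return FoldAssignment("random", n_folds, assignment, seed)


def tripwise_stratify(features: pd.DataFrame, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Deal whole trips into folds, spreading per-activity trip counts evenly.

    For every activity the per-fold trip counts differ by at most one; which
    folds receive the extra trip is randomized by the seed.  Windows inherit
    their trip's fold.  An activity with fewer trips than folds leaves some
    folds without it (warned, not an error).
    """
    rng = np.random.default_rng(seed)
    trips = features[["trip", "activity"]].drop_duplicates().sort_values("trip")
    assignment: dict = {}
    for activity in ACTIVITIES:
        ids = trips.loc[trips["activity"] == activity, "trip"].to_numpy()
        if ids.size == 0:
            continue
        if ids.size < n_folds:
            logger.warning("activity %s has %d trips (< %d folds); some folds "
                           "will lack it", activity, ids.size, n_folds)
        perm = rng.permutation(ids)
        base, rem = divmod(ids.size, n_folds)
        sizes = np.full(n_folds, base, dtype=int)
        if rem:
            sizes[rng.choice(n_folds, size=rem, replace=False)] += 1
        pos = 0
        for f in range(n_folds):
            for trip_id in perm[pos: pos + sizes[f]]:
                assignment[trip_id] = f
            pos += sizes[f]
    return FoldAssignment("tripwise", n_folds, assignment, seed)


def _coverage_table(features: pd.DataFrame) -> pd.DataFrame:
    """Participant × activity window counts."""
    pivot = (features.groupby(["participant", "activity"], sort=True)
             .size().unstack(fill_value=0))
    for activity in ACTIVITIES:
        if activity not in pivot.columns:
            pivot[activity] = 0
    return pivot[list(ACTIVITIES)].sort_index()


def build_loso_bands(coverage: pd.DataFrame) -> list[ParticipantBand]:
    """Greedy coverage-completing merge of participants into bands.

    Input: participant × activity window counts (as from a feature table via
    the pivot used by :func:`loso_stratify`).  Every participant starts as a
    singleton band; while any band misses an activity present in the cohort,
    the smallest such band (ties by lowest participant id) is merged with
    the band contributing the most missing activities (ties by smallest band
    then lowest id).  Fails if an activity is covered by fewer than two
    participants, since then either the held-out band or its training
    complement must miss that activity.
    """
    present = [a for a in ACTIVITIES if coverage[a].sum() > 0]
    for activity in present:
        if (coverage[activity] > 0).sum() < 2:
            raise BandingError(
                f"activity {activity!r} is covered by fewer than two "
                "participants; no leave-out banding can cover it on both sides"
            )
    bands: list[list[str]] = [[p] for p in coverage.index]

    def covered(band: list[str]) -> set:
        return {a for a in present if coverage.loc[band, a].sum() > 0}

    while True:
        incomplete = [b for b in bands if covered(b) != set(present)]
        if not incomplete:
            break
        incomplete.sort(key=lambda b: (len(b), min(b)))
        target = incomplete[0]
        missing = set(present) - covered(target)
        candidates = [b for b in bands if b is not target]
        candidates.sort(key=lambda b: (-len(missing & covered(b)), len(b), min(b)))
        partner = candidates[0]
        bands.remove(target)
        bands.remove(partner)
        bands.append(sorted(target + partner))
    if len(bands) < 2:
        raise BandingError("banding collapsed to a single band; training "
                           "complement would be empty")
    bands.sort(key=min)
    return [
        ParticipantBand(
            band_id=i,
            participants=tuple(b),
            window_counts={a: int(coverage.loc[b, a].sum()) for a in ACTIVITIES},
        )
        for i, b in enumerate(bands)
    ]


def loso_stratify(features: pd.DataFrame) -> FoldAssignment:
    """Leave-one-band-out assignment derived from a feature table."""
    bands = build_loso_bands(_coverage_table(features))
    assignment = {p: band.band_id for band in bands for p in band.participants}
    return FoldAssignment("loso", len(bands), assignment, seed=0)


def stratify(features: pd.DataFrame, scheme: str, n_folds: int = 10,
             seed: int = 0) -> FoldAssignment:
    """Build a fold assignment for any of the three schemes."""
    if scheme == "random":
        return random_stratify(features, n_folds=n_folds, seed=seed)
    if scheme == "tripwise":
        return tripwise_stratify(features, n_folds=n_folds, seed=seed)
    if scheme == "loso":
        return loso_stratify(features)
    raise ConfigurationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def run_cross_validation(
    features: pd.DataFrame,
    assignment: FoldAssignment,
    classifier: ClassifierSpec | None = None,
    balance: BalanceConfig | None = None,
) -> pd.DataFrame:
    """Fit and predict every fold; return pooled test predictions.

    For each fold the training set is the complement; balancing (if any) is
    applied to the training rows only, after the leakage guard has verified
    that train and test row ids are disjoint.  The returned table has one
    row per feature-table row with its fold and predicted label, metadata
    retained for post-processing.
    """
    classifier = classifier or ClassifierSpec()
    balance = balance or BalanceConfig()
    folds = assignment.row_folds(features)
    outputs = []
    for f in sorted(set(folds)):
        test = features.iloc[folds == f]
        train = features.iloc[folds != f]
        overlap = set(train.index) & set(test.index)
        if overlap:
            raise LeakageError(
                f"fold {f}: {len(overlap)} row ids appear in both train and test"
            )
        if len(test) == 0 or len(train) == 0:
            raise StratificationError(f"fold {f} has an empty train or test side")
        try:
            balanced = balance_table(train, balance)
        except Exception as exc:
            raise type(exc)(f"fold {f}: {exc}") from exc
        if set(balanced.index) & set(test.index):
            raise LeakageError(f"fold {f}: balancing produced test row ids")
        try:
            predicted = fit_predict(classifier, balanced, test)
        except Exception as exc:
            raise type(exc)(f"fold {f}: {exc}") from exc
        block = test[["participant", "trip", "activity", "window_index"]].copy()
        block["fold"] = f
        block["predicted"] = predicted
        outputs.append(block)
    return pd.concat(outputs)
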