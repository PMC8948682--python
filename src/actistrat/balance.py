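"""Class rebalancing of TRAINING feature tables.

Four methods: downsample every class to the minority count, oversample every
class to the majority count, meet at the rounded mean count, or SMOTE
(synthetic minority oversampling: each synthetic row is a random point on
the segment between a minority row and one of its k nearest same-class
neighbours in Euclidean feature space).  SMOTE is implemented here directly
so its sampling is seed-stable and its geometry testable.

Balancing is only ever applied to training folds; the cross-validation
driver enforces that (see :mod:`actistrat.stratify`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import ACTIVITIES
from .exceptions import BalancingError, ConfigurationError

logger = logging.getLogger(__name__)

METHODS = ("none", "downsample", "oversample", "both", "smote")


@dataclass(frozen=True)
class BalanceConfig:
    method: str = "none"
    smote_k: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(
                f"method must be one of {METHODS}, got {self.method!r}"
            )
        if self.smote_k < 1:
            raise ConfigurationError("smote_k must be >= 1")


def _class_blocks(train: pd.DataFrame) -> list[tuple[str, pd.DataFrame]]:
    if len(train) == 0:
        raise BalancingError("cannot balance an empty training table")
    present = [a for a in ACTIVITIES if (train["activity"] == a).any()]
    extra = sorted(set(train["activity"]) - set(present))
    return [(a, train[train["activity"] == a]) for a in present + extra]


def downsample(train: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Reduce every class to the minority-class count (without replacement)."""
    rng = np.random.default_rng(seed)
    blocks = _class_blocks(train)
    target = min(len(b) for _, b in blocks)
    kept = [
        b if len(b) == target
        else b.iloc[np.sort(rng.choice(len(b), size=target, replace=False))]
        for _, b in blocks
    ]
    return pd.concat(kept)


def oversample(train: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Raise every class to the majority-class count by random duplication."""
    rng = np.random.default_rng(seed)
    blocks = _class_blocks(train)
    target = max(len(b) for _, b in blocks)
    parts = []
    for _, b in blocks:
        parts.append(b)
        if len(b) < target:
            parts.append(b.iloc[rng.integers(0, len(b), size=target - len(b))])
    return pd.concat(parts)


def balance_both(train: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Over- and downsample so every class meets the rounded mean count."""
    rng = np.random.default_rng(seed)
    blocks = _class_blocks(train)
    target = int(round(float(np.mean([len(b) for _, b in blocks]))))
    parts = []
    for _, b in blocks:
        if len(b) > target:
            parts.append(b.iloc[np.sort(rng.choice(len(b), size=target, replace=False))])
        else:
            parts.append(b)
            if len(b) < target:
                parts.append(b.iloc[rng.integers(0, len(b), size=target - len(b))])
    return pd.concat(parts)


def smote(train: pd.DataFrame, k: int = 5, seed: int = 0) -> pd.DataFrame:
    """Raise minority classes to the majority count with synthetic rows.

    Each synthetic row is ``x + u·(z − x)`` for a seeded random minority row
    x, one of its k nearest same-class neighbours z (Euclidean distance over
    the feature columns), and u uniform on [0, 1].  Metadata is copied from
    x and the row is flagged in the ``synthetic`` column.  A class with a
    single member falls back to duplication; k is reduced to class size − 1
    when necessary (both logged).
    """
    rng = np.random.default_rng(seed)
    blocks = _class_blocks(train)
    target = max(len(b) for _, b in blocks)
    feature_cols = [c for c in train.columns
                    if c not in ("participant", "trip", "activity",
                                 "window_index", "synthetic")]
    next_id = (int(train.index.max()) + 1
               if len(train) and pd.api.types.is_numeric_dtype(train.index) else 0)
    parts = []
    for activity, b in blocks:
        parts.append(b)
        need = target - len(b)
        if need == 0:
            continue
        if len(b) == 1:
            logger.warning("class %s has a single row; SMOTE falls back to duplication",
                           activity)
            dup = pd.concat([b] * need)
            parts.append(dup)
            continue
        k_eff = min(k, len(b) - 1)
        if k_eff < k:
            logger.warning("class %s: k reduced from %d to %d (class size %d)",
                           activity, k, k_eff, len(b))
        x = b[feature_cols].to_numpy(dtype=float)
        dist = cdist(x, x)
        np.fill_diagonal(dist, np.inf)
        neighbours = np.argsort(dist, axis=1, kind="stable")[:, :k_eff]
        seeds_i = rng.integers(0, len(b), size=need)
        picks = neighbours[seeds_i, rng.integers(0, k_eff, size=need)]
        u = rng.uniform(0.0, 1.0, size=need)
        synth_feats = x[seeds_i] + u[:, None] * (x[picks] - x[seeds_i])
        synth = b.iloc[seeds_i].copy()
        synth[feature_cols] = synth_feats
        if "synthetic" in synth.columns:
            synth["synthetic"] = True
        synth.index = range(next_id, next_id + need)
        next_id += need
        parts.append(synth)
    return pd.concat(parts)


def balance_table(train: pd.DataFrame, config: BalanceConfig) -> pd.DataFrame:
    """Dispatch to the configured balancing method (``none`` is identity)."""
    config.validate()
    if config.method == "none":
        return train
    if config.method == "downsample":
        return downsample(train, seed=config.seed)
    if config.method == "oversample":
        return oversample(train, seed=config.seed)
    if config.method == "both":
        return balance_both(train, seed=config.seed)
    return smote(train, k=config.smote_k, seed=config.seed)


def balance_report(before: pd.DataFrame, after: pd.DataFrame) -> pd.DataFrame:
    """Per-class row counts before and after balancing."""
    b = before["activity"].value_counts()
    a = after["activity"].value_counts()
    classes = [c for c in ACTIVITIES if c in b.index or c in a.index]
    return pd.DataFrame({
        "activity": classes,
        "before": [int(b.get(c, 0)) for c in classes],
        "after": [int(a.get(c, 0)) for c in classes],
    })
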