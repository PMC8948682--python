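"""Pre-processing: 1 Hz resampling, base signals, outlier removal, duration filter.

Raw streams arrive at heterogeneous per-device sampling rates; every trip is
scaled down to 1 Hz by averaging the samples falling in each integer second.
From the resampled axes two orientation-derived base signals follow: the
resultant acceleration ``accR = sqrt(ax² + ay² + az²)`` (rotation-invariant)
and the direction cosines ``ci = ai / accR`` (orientation of the net
acceleration in the device frame).  Outliers are removed per trip with a
Tukey fence on accR, and trips left with fewer than 30 one-second records
are excluded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError

logger = logging.getLogger(__name__)

BASE_SIGNALS = ("ax", "ay", "az", "accR", "cx", "cy", "cz")


def resample_to_1hz(samples: pd.DataFrame) -> pd.DataFrame:
    """Average one trip's raw samples into one record per integer second.

    Each axis of the output record at second ``s`` is the arithmetic mean of
    the raw samples with ``floor(timestamp) == s``; seconds containing no raw
    samples yield no record (a gap).  Metadata columns are carried through.
    """
    if len(samples) == 0:
        raise EmptyInputError("cannot resample an empty trip")
    second = np.floor(samples["timestamp"].to_numpy()).astype(np.int64)
    grouped = (
        samples.assign(timestamp=second)
        .groupby("timestamp", sort=True, as_index=False)
        .agg({"participant": "first", "trip": "first", "activity": "first",
              "ax": "mean", "ay": "mean", "az": "mean"})
    )
    return grouped[["participant", "trip", "activity", "timestamp", "ax", "ay", "az"]]


def compute_base_signals(samples: pd.DataFrame) -> pd.DataFrame:
    """Append accR and direction cosines to resampled records.

    A zero acceleration vector gets ``accR = 0`` and cosines ``(0, 0, 0)``
    by convention.
    """
    out = samples.copy()
    axes = out[["ax", "ay", "az"]].to_numpy(dtype=float)
    acc_r = np.linalg.norm(axes, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = np.where(acc_r[:, None] > 0, axes / acc_r[:, None], 0.0)
    out["accR"] = acc_r
    out["cx"] = cos[:, 0]
    out["cy"] = cos[:, 1]
    out["cz"] = cos[:, 2]
    return out


def remove_outliers(signals: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Drop records of one trip whose accR falls outside the Tukey fence.

    The fence is ``[Q1 - k*IQR, Q3 + k*IQR]`` of the trip's own accR
    distribution (quartiles by linear interpolation).  Trips shorter than 4
    records pass through unchanged with a logged warning; order is preserved.
    """
    if len(signals) < 4:
        logger.warning(
            "trip %s has %d records (< 4); outlier removal skipped",
            signals["trip"].iloc[0] if len(signals) else "<empty>", len(signals),
        )
        return signals
    acc_r = signals["accR"].to_numpy(dtype=float)
    q1, q3 = np.percentile(acc_r, [25.0, 75.0])
    iqr = q3 - q1
    keep = (acc_r >= q1 - k * iqr) & (acc_r <= q3 + k * iqr)
    return signals.loc[keep]


def filter_min_duration(
    trips: pd.DataFrame, threshold_s: int = 30
) -> tuple[pd.DataFrame, list[str]]:
    """Exclude trips with fewer than ``threshold_s`` one-second records.

    Returns the kept records and the sorted list of excluded trip ids.
    """
    counts = trips.groupby("trip", sort=False).size()
    excluded = sorted(counts.index[counts < threshold_s])
    kept = trips[~trips["trip"].isin(excluded)]
    return kept, excluded


def preprocess_cohort(
    cohort: pd.DataFrame,
    outlier_k: float = 3.0,
    min_duration_s: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full pre-processing chain on a raw cohort.

    Per trip: resample to 1 Hz, derive base signals, remove accR outliers;
    then apply the minimum-duration filter cohort-wide.  Returns the cleaned
    1 Hz table and a per-trip report (records before/after, kept flag).
    """
    if len(cohort) == 0:
        raise EmptyInputError("cannot preprocess an empty cohort")
    processed = []
    report_rows = []
    for trip_id, block in cohort.groupby("trip", sort=True):
        resampled = resample_to_1hz(block)
        signals = remove_outliers(compute_base_signals(resampled), k=outlier_k)
        processed.append(signals)
        report_rows.append({
            "trip": trip_id,
            "participant": block["participant"].iloc[0],
            "activity": block["activity"].iloc[0],
            "raw_records": len(block),
            "resampled_records": len(resampled),
            "clean_records": len(signals),
        })
    clean = pd.concat(processed, ignore_index=True)
    kept, excluded = filter_min_duration(clean, threshold_s=min_duration_s)
    report = pd.DataFrame(report_rows)
    report["kept"] = ~report["trip"].isin(excluded)
    if excluded:
        logger.info("minimum-duration filter excluded %d trips", len(excluded))
    return kept.reset_index(drop=True), report
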