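"""Sliding-window feature extraction.

Each trip's 1 Hz base signals are cut into fixed-length windows (default
28 s, 75% overlap) and every window is summarized by 25 order-free
statistics of each of the 7 signals (ax, ay, az, accR, cx, cy, cz):
mean, maximum, minimum, standard deviation, skewness, kurtosis, and the
percentiles 5%, 10%, …, 90%, 95% — 175 features in total.

Conventions (fixed here because several are ambiguous in common usage):
sample standard deviation (denominator n−1); moment-based sample skewness
g1 = m3 / m2^1.5; Fisher excess kurtosis m4 / m2² − 3; skewness and kurtosis
of a constant window are defined as 0; percentiles use linear interpolation.
Windows never span a resampling gap, and trailing partial windows are
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sps

from .constants import METADATA_COLUMNS
from .exceptions import ConfigurationError, ContractError
from .preprocess import BASE_SIGNALS

logger = logging.getLogger(__name__)

PERCENTILES = tuple(range(5, 100, 5))  # 5, 10, ..., 95 → 19 values

STAT_NAMES = ("mean", "max", "min", "std", "skew", "kurt") + tuple(
    f"p{q:02d}" for q in PERCENTILES
)

#: The 175 feature column names, signal-major then statistic.
FEATURE_COLUMNS = tuple(
    f"{sig}_{stat}" for sig in BASE_SIGNALS for stat in STAT_NAMES
)

N_FEATURES = len(FEATURE_COLUMNS)


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: length in seconds and overlap fraction.

    The step between window starts is ``round(window_s * (1 - overlap))``,
    floored at 1.
    """

    window_s: int = 28
    overlap: float = 0.75

    def validate(self) -> None:
        if self.window_s < 2:
            raise ConfigurationError("window_s must be >= 2")
        if not 0.0 < self.overlap < 1.0:
            raise ConfigurationError("overlap must be strictly between 0 and 1")

    @property
    def step(self) -> int:
        return max(1, int(round(self.window_s * (1.0 - self.overlap))))


def _contiguous_runs(seconds: np.ndarray) -> list[slice]:
    """Slices of maximal runs of consecutive integer seconds."""
    if seconds.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(seconds) != 1) + 1
    edges = np.concatenate(([0], breaks, [seconds.size]))
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _window_stats(windows: np.ndarray) -> np.ndarray:
    """Statistics for a stack of windows, shape (n, n_signals, window_s).

    Returns (n, n_signals * 25) in signal-major order.
    """
    mean = windows.mean(axis=-1)
    wmax = windows.max(axis=-1)
    wmin = windows.min(axis=-1)
    std = windows.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = sps.skew(windows, axis=-1, bias=True)
        kurt = sps.kurtosis(windows, axis=-1, fisher=True, bias=True)
    constant = std == 0.0
    skew = np.where(constant, 0.0, np.nan_to_num(skew))
    kurt = np.where(constant, 0.0, np.nan_to_num(kurt))
    pct = np.percentile(windows, PERCENTILES, axis=-1)  # (19, n, n_signals)
    blocks = [mean, wmax, wmin, std, skew, kurt] + [pct[i] for i in range(len(PERCENTILES))]
    stacked = np.stack(blocks, axis=-1)  # (n, n_signals, 25)
    return stacked.reshape(windows.shape[0], -1)


def window_trip(signals: pd.DataFrame, config: WindowConfig) -> list[pd.DataFrame]:
    """Cut one trip's base signals into ordered, fully contained windows.

    Windows start at offsets 0, step, 2·step, … within each contiguous
    (gap-free) run of seconds; a trip shorter than the window yields an
    empty list (logged, not an error).
    """
    config.validate()
    w, step = config.window_s, config.step
    seconds = signals["timestamp"].to_numpy(dtype=np.int64)
    out: list[pd.DataFrame] = []
    for run in _contiguous_runs(seconds):
        length = run.stop - run.start
        for off in range(0, length - w + 1, step):
            out.append(signals.iloc[run.start + off: run.start + off + w])
    if not out:
        logger.info(
            "trip %s shorter than the %d s window in every contiguous run",
            signals["trip"].iloc[0] if len(signals) else "<empty>", w,
        )
    return out


def extract_features(window: pd.DataFrame, config: WindowConfig | None = None) -> pd.Series:
    """The 175-value feature vector of one window, as a named Series."""
    config = config or WindowConfig()
    if len(window) != config.window_s:
        raise ContractError(
            f"window has {len(window)} records, expected {config.window_s}"
        )
    arr = window[list(BASE_SIGNALS)].to_numpy(dtype=float).T[None]  # (1, 7, w)
    return pd.Series(_window_stats(arr)[0], index=list(FEATURE_COLUMNS))


def build_feature_table(signals: pd.DataFrame, config: WindowConfig | None = None) -> pd.DataFrame:
    """Feature table of a whole cohort of preprocessed trips.

    One row per window, metadata columns (participant, trip, activity,
    window_index, synthetic) followed by the 175 feature columns.  The row
    index is a unique window id.
    """
    config = config or WindowConfig()
    config.validate()
    w, step = config.window_s, config.step
    meta_rows = []
    blocks = []
    for trip_id, block in signals.groupby("trip", sort=True):
        arr = block[list(BASE_SIGNALS)].to_numpy(dtype=float)
        seconds = block["timestamp"].to_numpy(dtype=np.int64)
        widx = 0
        for run in _contiguous_runs(seconds):
            length = run.stop - run.start
            if length < w:
                continue
            sw = sliding_window_view(arr[run], w, axis=0)  # (length-w+1, 7, w)
            offsets = np.arange(0, length - w + 1, step)
            blocks.append(_window_stats(sw[offsets]))
            for _ in offsets:
                meta_rows.append((
                    block["participant"].iloc[0], trip_id,
                    block["activity"].iloc[0], widx, False,
                ))
                widx += 1
    if not blocks:
        return pd.DataFrame(columns=list(METADATA_COLUMNS) + list(FEATURE_COLUMNS))
    meta = pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS))
    feats = pd.DataFrame(np.vstack(blocks), columns=list(FEATURE_COLUMNS))
    return pd.concat([meta, feats], axis=1)
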