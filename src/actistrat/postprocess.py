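"""Trip-scoped voting post-processor.

Within one trip, a running 4-class tally starts at zero.  Visiting the
predicted labels in sequence, the predicted class gains one vote and every
other class loses one, floored at zero; the instance's corrected label is
the argmax of the tally recorded right after its update.  Ties are broken
for continuity: the previously visited instance's corrected label wins if
it is among the maxima, then the instance's own predicted label, then the
first maximum in the fixed class order.  (Continuity-first is what makes a
deviant flanked by exactly two agreeing labels correctable — with the tally
tied 1:1 there, any tie-break favouring the instance's own label would let
the deviant survive every pass.)  Full smoothing chains three
passes — forward, backward, forward — each consuming the corrected labels
of the previous pass.  Trips are smoothed independently; tallies reset at
trip boundaries.

The smoother removes short mislabelled runs inside an otherwise coherent
trip (a single deviant label flanked by at least two agreeing labels on
each side is always corrected) while leaving homogeneous trips untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import ACTIVITIES, ACTIVITY_INDEX
from .exceptions import ContractError, EmptyInputError, UnknownLabelError


@dataclass
class VoteTrace:
    """Tallies (one row per instance, recorded after that instance's update,
    in original trip order) and the corrected labels of one voting pass."""

    tallies: np.ndarray  # shape (n, 4), int
    corrected: list[str]


def _encode(labels: Sequence[str]) -> list[int]:
    try:
        return [ACTIVITY_INDEX[l] for l in labels]
    except KeyError as exc:
        raise UnknownLabelError(f"unknown activity label {exc.args[0]!r}") from None


def vote_pass(labels: Sequence[str], direction: str = "forward") -> VoteTrace:
    """One voting pass over a single trip's predicted labels.

    ``direction`` chooses the visiting order; the returned trace is always
    in original trip order.
    """
    if direction not in ("forward", "backward"):
        raise ContractError(f"direction must be forward or backward, got {direction!r}")
    labels = list(labels)
    if not labels:
        raise EmptyInputError("vote_pass requires a non-empty trip")
    codes = _encode(labels)
    n = len(codes)
    order = range(n) if direction == "forward" else range(n - 1, -1, -1)
    tallies = np.zeros((n, len(ACTIVITIES)), dtype=int)
    corrected = [""] * n
    tally = np.zeros(len(ACTIVITIES), dtype=int)
    prev: int | None = None
    for i in order:
        new = np.maximum(tally - 1, 0)
        new[codes[i]] = tally[codes[i]] + 1
        tally = new
        tallies[i] = tally
        top = tally.max()
        if prev is not None and tally[prev] == top:
            winner = prev
        elif tally[codes[i]] == top:
            winner = codes[i]
        else:
            winner = int(np.argmax(tally))
        corrected[i] = ACTIVITIES[winner]
        prev = winner
    return VoteTrace(tallies=tallies, corrected=corrected)


def postprocess_trip(labels: Sequence[str]) -> list[str]:
    """Forward, backward, forward voting over one trip's predictions.

    Each pass consumes the previous pass's corrected labels.
    """
    first = vote_pass(labels, "forward")
    second = vote_pass(first.corrected, "backward")
    third = vote_pass(second.corrected, "forward")
    return third.corrected


def postprocess_predictions(predictions: pd.DataFrame,
                            label_column: str = "predicted") -> pd.DataFrame:
    """Apply the per-trip smoother to a predictions table.

    The table must carry a ``trip`` id on every row; instances are assumed
    ordered within each trip.  Returns a copy with a ``corrected`` column;
    row order is unchanged.
    """
    if "trip" not in predictions.columns:
        raise ContractError("predictions table lacks a trip column")
    if predictions["trip"].isna().any():
        raise ContractError("predictions table has rows with missing trip ids")
    out = predictions.copy()
    corrected = pd.Series(index=predictions.index, dtype=object)
    for _, block in predictions.groupby("trip", sort=False):
        corrected.loc[block.index] = postprocess_trip(block[label_column].tolist())
    out["corrected"] = corrected
    return out
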