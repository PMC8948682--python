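"""Shared constants.

The four-activity alphabet, in the fixed order used for confusion matrices,
vote tallies and argmax tie-breaking throughout the package.
"""

ACTIVITIES: tuple[str, ...] = ("inactive", "active", "walking", "driving")

ACTIVITY_INDEX: dict[str, int] = {a: i for i, a in enumerate(ACTIVITIES)}

#: Metadata columns of a feature table, in order, before the feature columns.
METADATA_COLUMNS: tuple[str, ...] = (
    "participant",
    "trip",
    "activity",
    "window_index",
    "synthetic",
)

#: Columns of the raw-cohort CSV dialect.
RAW_COLUMNS: tuple[str, ...] = (
    "participant",
    "trip",
    "activity",
    "timestamp",
    "ax",
    "ay",
    "az",
)
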