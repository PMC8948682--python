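import pandas as pd
import pytest

from actistrat import (
    GeneratorConfig,
    WindowConfig,
    build_feature_table,
    generate_cohort,
)
from actistrat.preprocess import preprocess_cohort


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A compact but structurally complete cohort configuration."""
    return GeneratorConfig(
        n_participants=6,
        trips_per_participant_per_activity=(1, 3),
        trip_duration_s=(50.0, 110.0),
        short_trip_fraction=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> pd.DataFrame:
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_signals(small_cohort) -> pd.DataFrame:
    clean, _ = preprocess_cohort(small_cohort)
    return clean


@pytest.fixture(scope="session")
def small_features(small_signals) -> pd.DataFrame:
    return build_feature_table(small_signals, WindowConfig())


def make_trip(values, trip="t0", participant="p0", activity="inactive"):
    """A minimal trip table from explicit (timestamp, ax, ay, az) rows."""
    if not values:
        return pd.DataFrame(columns=[
            "participant", "trip", "activity", "timestamp", "ax", "ay", "az"])
    ts, ax, ay, az = zip(*values)
    return pd.DataFrame({
        "participant": participant,
        "trip": trip,
        "activity": activity,
        "timestamp": list(ts),
        "ax": list(ax),
        "ay": list(ay),
        "az": list(az),
    })
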