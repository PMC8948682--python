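"""Synthetic smartphone-accelerometer cohort generator.

Emulates the structure of real-life activity-recognition recordings: each
participant contributes several single-activity episodes ("trips") recorded
at a participant-specific sampling rate, with the phone held in an unknown,
per-trip random orientation.  Participants carry individual movement
signatures (gait frequency and amplitude, fidgeting rate, vehicle-vibration
level) so that training on one participant genuinely transfers information
to that participant's other trips — the leakage structure the stratification
study is about.

Signal models per activity (world frame, gravity along +z, in m/s²):

* ``inactive``  — phone at rest: gravity plus sensor noise.
* ``active``    — phone carried while moving around one place: gravity under
  a slow orientation random walk, plus sporadic motion bursts.
* ``walking``   — gravity plus a sinusoidal gait component at the
  participant's cadence, a second harmonic, a smaller horizontal sway, and
  noise.  Includes jogging-like higher amplitudes.
* ``driving``   — gravity plus broadband vehicle vibration and sporadic
  longitudinal acceleration/braking events.

The per-trip device rotation is applied to the whole world-frame signal,
noise included, so the resultant acceleration of a trip is exactly invariant
under the rotation (isotropic noise makes this distributionally equivalent
to device-frame noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .constants import ACTIVITIES, RAW_COLUMNS
from .exceptions import ConfigurationError


def _default_mix() -> dict[str, float]:
    # Class shares of the real cohort this generator emulates:
    # inactive-dominated, walking/driving minorities.
    return {"inactive": 0.46, "active": 0.26, "walking": 0.14, "driving": 0.14}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of a synthetic cohort.

    Ranges are inclusive ``(low, high)`` pairs.  ``activity_mix`` gives the
    target share of *samples* per class; after the trip plan is drawn, the
    durations of each activity's trips are rescaled so the planned duration
    share equals the mix (renormalized over the activities that actually
    received trips), while trip counts stay governed by
    ``trips_per_participant_per_activity`` (a draw of 0 emulates a
    participant skipping that activity; a mix share of 0 drops the activity
    entirely).
    """

    n_participants: int = 12
    trips_per_participant_per_activity: tuple[int, int] = (0, 5)
    trip_duration_s: tuple[float, float] = (60.0, 180.0)
    sampling_rate_hz: tuple[float, float] = (8.0, 32.0)
    activity_mix: dict[str, float] = field(default_factory=_default_mix)
    noise_sd: float = 0.3
    gravity: float = 9.81
    short_trip_fraction: float = 0.02
    short_trip_duration_s: tuple[float, float] = (12.0, 25.0)
    random_rotation: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        for name in ("trips_per_participant_per_activity", "trip_duration_s",
                     "sampling_rate_hz", "short_trip_duration_s"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ConfigurationError(f"{name} must be a non-empty non-negative range")
        if self.sampling_rate_hz[0] <= 0:
            raise ConfigurationError("sampling_rate_hz must be strictly positive")
        if self.trip_duration_s[0] <= 0:
            raise ConfigurationError("trip_duration_s must be strictly positive")
        if set(self.activity_mix) != set(ACTIVITIES):
            raise ConfigurationError("activity_mix must have exactly the four activity keys")
        if any(v < 0 for v in self.activity_mix.values()):
            raise ConfigurationError("activity_mix shares must be non-negative")
        if abs(sum(self.activity_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("activity_mix shares must sum to 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.gravity <= 0:
            raise ConfigurationError("gravity must be strictly positive")
        if not 0.0 <= self.short_trip_fraction < 1.0:
            raise ConfigurationError("short_trip_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ParticipantSignature:
    """Per-participant movement signature, drawn once per participant.

    These values are what makes a participant's trips mutually predictable:
    a model that has seen one walking trip of a participant has effectively
    seen that participant's cadence.
    """

    gait_frequency: float  # Hz, step fundamental
    gait_amplitude: float  # m/s², vertical gait component
    activity_burst_rate: float  # bursts/min while "active"
    drive_vibration_sd: float  # m/s², broadband vehicle vibration

    def __post_init__(self) -> None:
        for name in ("gait_frequency", "gait_amplitude",
                     "activity_burst_rate", "drive_vibration_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")


def draw_signature(rng: np.random.Generator) -> ParticipantSignature:
    """Draw one participant's signature from the population distributions."""
    return ParticipantSignature(
        gait_frequency=rng.uniform(1.4, 2.2),
        gait_amplitude=rng.uniform(1.5, 3.5),
        activity_burst_rate=rng.uniform(2.0, 8.0),
        drive_vibration_sd=rng.uniform(0.5, 1.5),
    )


def _random_rotation(rng: np.random.Generator) -> Rotation:
    # Uniform rotation via a normalized Gaussian quaternion.
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q))


def _gaussian_bumps(t: np.ndarray, centers: np.ndarray, widths: np.ndarray,
                    amplitudes: np.ndarray) -> np.ndarray:
    """Sum of per-axis Gaussian bumps; amplitudes has shape (k, 3)."""
    out = np.zeros((t.size, 3))
    for c, w, a in zip(centers, widths, amplitudes):
        out += np.exp(-0.5 * ((t - c) / w) ** 2)[:, None] * a[None, :]
    return out


def _world_signal(activity: str, t: np.ndarray, duration: float,
                  sig: ParticipantSignature, gravity: float,
                  rng: np.random.Generator) -> np.ndarray:
    n = t.size
    world = np.zeros((n, 3))
    world[:, 2] = gravity
    if activity == "inactive":
        pass
    elif activity == "active":
        # Slow orientation random walk of the gravity direction.
        fs = n / duration if duration > 0 else 1.0
        steps = rng.normal(0.0, 0.015 / math.sqrt(fs), size=(n, 3))
        world = Rotation.from_rotvec(np.cumsum(steps, axis=0)).apply(world)
        k = rng.poisson(sig.activity_burst_rate / 60.0 * duration)
        if k > 0:
            centers = rng.uniform(0.0, duration, k)
            widths = rng.uniform(0.3, 1.2, k)
            amps = rng.normal(0.0, 2.0, (k, 3))
            world += _gaussian_bumps(t, centers, widths, amps)
    elif activity == "walking":
        f = sig.gait_frequency
        a = sig.gait_amplitude
        ph = rng.uniform(0.0, 2.0 * math.pi, 3)
        world[:, 2] += a * np.sin(2.0 * math.pi * f * t + ph[0])
        world[:, 2] += 0.3 * a * np.sin(2.0 * math.pi * 2.0 * f * t + ph[1])
        world[:, 0] += 0.3 * a * np.sin(2.0 * math.pi * f * t + ph[2])
    elif activity == "driving":
        world += rng.normal(0.0, sig.drive_vibration_sd, (n, 3))
        k = rng.poisson(2.5 / 60.0 * duration)
        if k > 0:
            centers = rng.uniform(0.0, duration, k)
            widths = rng.uniform(1.0, 4.0, k)
            amps = np.zeros((k, 3))
            amps[:, 0] = rng.uniform(1.0, 2.5, k) * rng.choice([-1.0, 1.0], k)
            world += _gaussian_bumps(t, centers, widths, amps)
    else:  # pragma: no cover - plan only contains known activities
        raise ConfigurationError(f"unknown activity {activity!r}")
    return world


def participant_signatures(config: GeneratorConfig) -> list[tuple[float, ParticipantSignature]]:
    """The (sampling rate, signature) pairs a config's cohort will use.

    Recomputed from the seed exactly as :func:`generate_cohort` does, so the
    ground-truth cadence of participant ``p%02d`` can be recovered.
    """
    config.validate()
    sig_ss = np.random.SeedSequence(config.seed).spawn(3)[0]
    rng_sig = np.random.default_rng(sig_ss)
    out = []
    for _ in range(config.n_participants):
        rate = float(rng_sig.uniform(*config.sampling_rate_hz))
        out.append((rate, draw_signature(rng_sig)))
    return out


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a labelled raw-accelerometer cohort.

    Returns one DataFrame with columns
    ``participant, trip, activity, timestamp, ax, ay, az`` where each trip is
    a contiguous block of monotonically increasing timestamps (seconds since
    trip start) at the participant's sampling rate.  Identical ``config``
    (including the seed) yields a byte-identical table.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    sig_ss, plan_ss, trips_ss = root.spawn(3)
    rng_sig = np.random.default_rng(sig_ss)
    rng_plan = np.random.default_rng(plan_ss)

    signatures: list[ParticipantSignature] = []
    rates: list[float] = []
    for _ in range(config.n_participants):
        rates.append(float(rng_sig.uniform(*config.sampling_rate_hz)))
        signatures.append(draw_signature(rng_sig))

    # Trip plan: (participant index, activity, base duration).
    lo, hi = config.trips_per_participant_per_activity
    plan: list[tuple[int, str, float]] = []
    for p in range(config.n_participants):
        for activity in ACTIVITIES:
            n_trips = int(rng_plan.integers(lo, hi + 1))
            if config.activity_mix[activity] == 0:
                continue
            for _ in range(n_trips):
                plan.append((p, activity, float(rng_plan.uniform(*config.trip_duration_s))))

    # Rescale durations so the planned duration share of each activity
    # equals its (renormalized) mix share.
    base_total = {a: 0.0 for a in ACTIVITIES}
    for _, activity, base in plan:
        base_total[activity] += base
    present = [a for a in ACTIVITIES if base_total[a] > 0]
    if present:
        grand = sum(base_total[a] for a in present)
        mix_norm = sum(config.activity_mix[a] for a in present)
        factor = {a: config.activity_mix[a] / mix_norm * grand / base_total[a]
                  for a in present}
        # Keep rescaled trips above the downstream duration filter.
        floor_s = 31.0
        plan = [(p, a, max(floor_s, base * factor[a])) for p, a, base in plan]

    # Plant short trips (below the downstream minimum-duration threshold).
    n_short = int(round(config.short_trip_fraction * len(plan)))
    if n_short > 0:
        short_idx = rng_plan.choice(len(plan), size=n_short, replace=False)
        for i in short_idx:
            p, activity, _ = plan[i]
            plan[i] = (p, activity, float(rng_plan.uniform(*config.short_trip_duration_s)))

    frames: list[pd.DataFrame] = []
    children = trips_ss.spawn(len(plan)) if plan else []
    trip_counter: dict[int, int] = {}
    for (p, activity, duration), child in zip(plan, children):
        rot_ss, sig_stream_ss = child.spawn(2)
        rng_trip = np.random.default_rng(sig_stream_ss)
        fs = rates[p]
        n = max(1, int(round(duration * fs)))
        t = np.arange(n) / fs
        world = _world_signal(activity, t, duration, signatures[p],
                              config.gravity, rng_trip)
        if config.noise_sd > 0:
            world = world + rng_trip.normal(0.0, config.noise_sd, (n, 3))
        if config.random_rotation:
            device = _random_rotation(np.random.default_rng(rot_ss)).apply(world)
        else:
            device = world
        k = trip_counter.get(p, 0)
        trip_counter[p] = k + 1
        frames.append(pd.DataFrame({
            "participant": f"p{p:02d}",
            "trip": f"p{p:02d}-t{k:03d}",
            "activity": activity,
            "timestamp": t,
            "ax": device[:, 0],
            "ay": device[:, 1],
            "az": device[:, 2],
        }))

    if not frames:
        return pd.DataFrame(columns=list(RAW_COLUMNS))
    return pd.concat(frames, ignore_index=True)[list(RAW_COLUMNS)]


def write_cohort(cohort: pd.DataFrame, path, per_participant: bool = False) -> list:
    """Write a cohort as CSV; one file, or one per participant.

    Returns the list of paths written.
    """
    from pathlib import Path

    path = Path(path)
    if not per_participant:
        cohort.to_csv(path, index=False)
        return [path]
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for pid, block in cohort.groupby("participant", sort=True):
        p = path / f"{pid}.csv"
        block.to_csv(p, index=False)
        written.append(p)
    return written


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    missing = set(RAW_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"cohort file missing columns: {sorted(missing)}")
    return df[list(RAW_COLUMNS)]
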