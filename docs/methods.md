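# Methods

## Problem and pipeline

The package studies four-class human activity recognition (inactive, active,
walking, driving) from a single smartphone accelerometer, under realistic
conditions: uncontrolled device orientation, heterogeneous sampling rates
across devices, strong class imbalance, and recordings organised as
single-activity episodes ("trips") per participant. The pipeline is

1. resample to 1 Hz → derive base signals → outlier removal → duration filter
2. sliding-window feature extraction (175 features)
3. stratification into cross-validation folds at one of three
   information-sharing levels
4. class balancing of the training folds only
5. classification
6. per-trip voting post-processing
7. per-class and overall metrics, aggregated over folds.

Its central object of study is *information sharing* between training and
test data, which operates at three nested levels: overlapping windows of one
trip (75% of adjacent windows' samples are shared), within-trip trends (a
fixed device orientation and signal regime per trip), and participant
signatures (a person's cadence and movement style recur across their trips).
Random window-level stratification shares all three with the training set;
trip-wise stratification only the participant level; leave-one-subject-out
(LOSO) none. The headline, seed-robust result on synthetic cohorts is the
monotone accuracy ordering random ≥ trip-wise ≥ LOSO.

## Pre-processing conventions

* **Resampling.** One output record per integer second (floor of the
  timestamp), each axis the arithmetic mean of that second's raw samples.
  Seconds with no samples produce gaps; windows never span a gap. Timestamps
  are seconds since trip start; absolute clocks are out of scope.
* **Base signals.** `accR = ‖(ax, ay, az)‖₂` and direction cosines
  `ci = ai/accR`; the degenerate zero vector gets cosines (0, 0, 0).
* **Outlier removal** is a per-trip Tukey fence on `accR` with multiplier
  k = 3 (configurable). A per-trip fence is scale-free and removes the spiky
  transients outlier screens in this domain target; whether screening should
  instead pool per activity or globally is an open design point — per-trip
  was chosen because trips are the natural stationarity unit here. Trips
  shorter than 4 records pass through with a warning.
* **Duration filter.** Trips with fewer than 30 one-second records after
  cleaning are excluded and reported.

## Features

25 order-free statistics — mean, max, min, sample standard deviation
(n − 1), moment-based sample skewness g₁ = m₃/m₂^1.5, Fisher excess kurtosis
m₄/m₂² − 3, and the 19 percentiles 5%…95% (linear interpolation) — of each
of 7 signals: the three raw axes plus `accR, cx, cy, cz`. The 7-signal × 25
layout is the only arithmetic that yields the 175-feature total this design
targets; skewness and kurtosis of a constant window are defined as 0.
Feature columns are named `<signal>_<stat>` in signal-major order.

Window length defaults to 28 s with 75% overlap; the step is
`round(window_s × (1 − overlap))`, floored at 1. A window is emitted only if
fully contained in a gap-free run; the count per run of length L is
`floor((L − w)/step) + 1`.

## Stratification

* **Random:** per activity, windows are shuffled (seeded) and dealt so the
  first nine folds receive exactly `floor(n/10)` windows and the tenth the
  remainder. An activity with fewer windows than folds is an error.
* **Trip-wise:** per activity, whole trips are dealt so per-fold trip counts
  differ by at most one, ignoring trip lengths; which folds take the extra
  trip is seeded. Windows inherit their trip's fold.
* **LOSO bands:** participants who skip activities cannot be held out alone
  (their fold would miss classes, or the training complement would). Bands
  are built by a deterministic greedy merge: every participant starts as a
  singleton; while any band misses a present activity, the smallest such
  band (ties by lowest participant id) merges with the band covering the
  most of its missing activities (ties by size, then id). An activity
  covered by fewer than two participants is an error: no banding can place
  it on both sides of a split.

The cross-validation driver refuses to proceed if train and test row ids
intersect, and re-checks after balancing — the leakage concern is enforced
in code, not just documented.

## Balancing (training folds only)

Downsampling to the minority count, oversampling to the majority count,
meeting at `round(mean class count)`, or SMOTE. SMOTE is implemented
directly (not via a library) so it is seed-stable and its geometry is
testable: each synthetic row is `x + u·(z − x)` with x a seeded random
minority row, z one of its k = 5 nearest same-class Euclidean neighbours and
u uniform on [0, 1]. Synthetic rows copy the seed row's metadata and are
flagged in the `synthetic` column; a singleton class falls back to
duplication and k is clipped to class size − 1 (both logged). Default
per-scheme choices in the experiment driver: oversampling under random
stratification, downsampling under trip-wise and LOSO — simple methods are
competitive here and downsampling also shrinks training cost.

## Classification and metrics

Learner internals are delegated to xgboost/scikit-learn behind a
name-keyed registry; the package owns the contract, label encoding in fixed
class order, seeding, and defaults. The default is gradient-boosted trees
(60 trees, depth 4, hist method, single thread) — accurate on these tabular
features at low compute. The feed-forward network entry
(64/32 hidden units, standardized inputs, 300 iterations) is a
package-chosen configuration. A minimal grid hook enumerates the Cartesian
product of a user-supplied hyperparameter grid.

Per class, the one-vs-rest reduction gives precision TP/(TP+FP), recall
TP/(TP+FN), F-score (harmonic mean), and a one-vs-rest accuracy
(TP+TN)/total. The overall accuracy reported in comparisons is the
multiclass trace/total; the two notions are deliberately computed and
labelled separately because they are easy to conflate. Zero-denominator
ratios are reported as 0 and flagged. Fold aggregation reports the
arithmetic mean and sample SD (n − 1; 0 for a single fold).

## Voting post-processor

Within one trip, a 4-class tally starts at zero; visiting instances in pass
order, the instance's label gains one vote and each other class loses one,
floored at zero. The corrected label is the tally argmax recorded
immediately after the update. Full smoothing chains forward, backward and
forward passes, each consuming the previous pass's corrected labels — the
chaining that reproduces the reference worked example, whose backward
tallies are only attainable from the forward-corrected sequence. Tallies
reset at trip boundaries, so test-time trip identity is an interface
requirement.

**Tie-breaking.** Argmax ties are broken for continuity: the previously
visited instance's corrected label wins if tied for the maximum, then the
instance's own input label, then fixed class order. Continuity-first is
load-bearing: a deviant label flanked by exactly two agreeing labels ties
its tally (1 vs 1) at its own instance in every pass, so any tie-break that
prefers the instance's input label would preserve the deviant forever,
breaking the guarantee that isolated errors flanked by ≥ 2 agreeing labels
are always corrected (verified exhaustively in tests for trips up to length
8). The worked example contains no ties and is unaffected.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
biomechanics:

* **Participant signatures** (drawn once per participant, seeded): gait
  frequency U(1.4, 2.2) Hz, gait amplitude U(1.5, 3.5) m/s², activity burst
  rate U(2, 8)/min, driving vibration SD U(0.5, 1.5) m/s². These create the
  participant-level information sharing LOSO is meant to remove.
* **Per-trip random device orientation** (uniform rotation), applied to the
  whole world-frame signal including the isotropic sensor noise
  (σ = 0.3 m/s² per axis by default), so `accR` is exactly
  rotation-invariant. Orientation also drifts slowly (random walk) during
  "active" trips.
* **Signal models** (world frame, gravity 9.81 m/s² on +z): inactive —
  gravity + noise; active — gravity under orientation drift + sporadic
  Gaussian motion bursts; walking — gravity + gait sinusoid at the
  participant's cadence + a 30% second harmonic + 30% horizontal sway;
  driving — gravity + broadband vibration + sporadic longitudinal
  acceleration/braking events (~2.5/min).
* **Cohort structure:** per participant, a per-activity trip count drawn
  from 0–5 (a 0 emulates a skipped activity, exercising LOSO banding), a
  per-participant sampling rate U(8, 32) Hz, and base trip durations
  U(60, 180) s. After the plan is drawn, durations are rescaled per activity
  so planned duration shares match the target class mix (46/26/14/14% for
  inactive/active/walking/driving), floored at 31 s; ~2% of trips are
  replaced by 12–25 s short trips to exercise the duration filter. The
  default cohort is 12 participants, ≈120 trips, ≈1.5 k windows — sized so
  a full three-scheme experiment runs in well under a minute per seed on
  one core while leaving every downstream contract exercised.

Noise magnitudes and signature distributions are free parameters chosen once
as plausible smartphone-accelerometer values; they are not calibrated to any
real dataset. What passing tests show is therefore that the *pipeline*
behaves as specified and that the information-sharing hierarchy emerges
whenever participant signatures, trip-level orientation and window overlap
carry signal; they do not certify accuracy levels on real recordings, where
activity confusability (e.g. jogging vs. slow vehicles) is far harsher.

## Numerical and degenerate-input choices

* Identical seed + config ⇒ byte-identical cohorts (per-trip seed streams
  are spawned deterministically; rotation and signal streams are separate so
  disabling rotation does not change the signal draw).
* Constant windows: std = skewness = kurtosis = 0; percentiles equal the
  constant.
* `accR = 0` ⇒ cosines (0, 0, 0).
* Quartiles/percentiles everywhere use linear interpolation.
* Fixed class order (inactive, active, walking, driving) governs label
  encoding, confusion-matrix axes, vote tallies and final tie-breaks.

## Known limitations

* Single sensor only; no gyroscope/GPS fusion, no gravity separation or
  axis recalibration.
* The generator's four signal models are stylized; no intra-trip activity
  switching, no traffic or terrain structure.
* The trip-wise dealing rule generalizes the even-count split; it does not
  reproduce any particular historical fold table.
* The neural-network registry entry is a baseline configuration, not a tuned
  architecture.
* Window-size/overlap sweeps report accuracy only; computation-time
  benchmarking is out of scope.
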