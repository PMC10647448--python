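# Methods

## The problem

Hospitalized cancer patients deteriorate abruptly — the composite endpoint
here is in-hospital cardiac arrest (IHCA) or unexpected ICU transfer — and
conventional track-and-trigger scores such as MEWS discriminate poorly in
this population. `canews` implements a recurrent-network early-warning score
built from the five routinely charted vitals (systolic blood pressure, heart
rate, respiratory rate, body temperature, AVPU consciousness), evaluates it
against a configurable MEWS baseline, and ships a seeded ward-cohort
simulator so the entire pipeline is testable without protected records.

## Data model and preprocessing

A stay is a time-ordered series of charted observations inside an
admission–discharge interval plus an outcome record (deteriorated or not;
event time and type when yes; only a stay's first event counts).

**Cleaning.** Values outside closed plausibility ranges become missing:
SBP 30–300 mmHg, HR 10–300 /min, RR 3–60 /min, BT 30–45 °C (an optional DBP
column is cleaned at 40–120 mmHg but never modelled). Cleaning is idempotent
and logged per variable.

**Hourly grid.** The grid starts at the first observation's hour (truncated
to the whole hour) and steps hourly to min(discharge, event time). Each
variable resolves to the charted value closest to — i.e. most recent at or
before — the grid point, carried forward across gaps. Hours before a
variable's first measurement are back-filled from that first value; a
variable never charted in a stay takes a physiologic default (SBP 120,
HR 80, RR 18, BT 36.5, alert) with a warning. Consciousness is encoded
ordinally A=0 … U=3.

**Deltas.** V2's five extra channels are consecutive hourly differences on
the resolved grid (not on raw irregular charting — the model consumes the
grid, so grid-level differences are what the sequence actually sees). The
delta at the first grid hour is 0, keeping every window's shape fixed;
cumulative summation recovers the level series exactly.

**Windows and labels.** A lookback-L window at grid hour t contains the L
most recent hourly vectors (oldest → newest) and is labeled positive iff t
lies between 30 minutes and 24 hours before the event. Hours inside the
30-minute blackout before the event are not emitted at all (too late to
act), and the grid itself ends at the event, so windows never contain
post-event information — a property the suite asserts bit-exactly. Stays
shorter than the lookback yield no windows rather than padded ones.

## The classifier

Three stacked GRU layers of 24 units, dropout 0.3 on each layer's output
sequence (training only), and a 2-unit softmax head; the event-class
probability × 100 is the 0–100 risk score. Training minimises binary
cross-entropy with Adam at its conventional defaults (lr 1e-3, β₁ 0.9,
β₂ 0.999). No class re-weighting is applied by default despite the heavy
imbalance; an optional `class_weight="balanced"` flag exists.

The network is implemented directly on NumPy arrays (forward,
backpropagation through time, Adam) in float32, with the logistic gate
computed via tanh for speed; a float64 mode backs the finite-difference
gradient check in the test suite. Feature channels are standardized to zero
mean and unit variance with statistics from the training windows only; the
frozen parameters are serialized with the weights. Training knobs the
architecture leaves open — epoch budget, batch size, early stopping — are
config fields (defaults: 50 epochs, batch 128, patience 5 on the monitored
loss, best parameters restored). With a fixed seed and thread
configuration, initialization, shuffling, dropout and therefore the whole
training history are bit-reproducible on the same platform.

## MEWS baseline

A table-agnostic banded scoring engine: per variable, closed-below/
open-above intervals worth 0–3 points that must partition the real line
(AVPU bands keyed by level), validated at load. The packaged default table
is transcribed from the published MEWS reference (Subbe et al., QJM 2001;
provenance stated in the YAML header) and sums to a maximum of 14; local
variants, including NEWS-style tables, load through the same YAML schema.

## Evaluation protocol

Scored observations: deteriorated stays contribute the hours from 24 h to
30 min pre-event labeled positive; non-deteriorated stays contribute all
serial hours (default for the recurrent scores) or a single per-patient
maximum (default for MEWS-style use, matching how aggregate scores are
screened in practice). Matched comparisons always run on identical
observation sets, enforced structurally by evaluating every score at the
same cross-validation windows.

* **AUROC** is the Mann–Whitney probability with ties counted 1/2; the 95%
  CI is a patient-level stratified bootstrap (cases and controls resampled
  separately; 1000 replicates by default, seeded). The bootstrap unit is
  the patient because serial hours within a stay are strongly dependent.
* **Correlated AUROC comparison**: a paired two-sided z-test whose variance
  uses the empirical covariance of placement values between the two scores,
  the consistent estimator for correlated-AUROC designs. Its type-I error
  at α=0.05 is verified by simulation in the suite.
* **Operating points** use the inclusive alarm rule score ≥ threshold.
  Matched-sensitivity thresholds take the largest threshold whose
  sensitivity reaches the target. **False alarms per day** divide control
  alarms by control observation-days (serial control hours / 24) — the
  denominator is a config choice since no canonical definition exists.
* **Cross-validation** is stratified at the stay level so no patient's
  windows straddle a fold boundary; per fold, each variant trains on the
  training stays' windows and scores the validation stays' windows, with
  MEWS computed on the same grid hours.
* The **lookback sweep** retrains per lookback and reports specificity and
  PPV at fixed sensitivities; the **risk trajectory** averages case scores
  per whole hour before the event (nearest grid hour within 30 min).

## The simulator

The generator emulates the statistical structure the method assumes, not
ward physiology. Defaults: admission vitals SBP 117.3 ± 19.8 mmHg,
HR 86.1 ± 19.7 /min, RR 18.9 ± 2.8 /min, BT 36.6 ± 0.5 °C, 99.8% alert;
4.5% of stays deteriorate; stay length log-normal with a 5.7-day median;
charting every ~2 h with jitter. Each population SD splits into a stable
patient baseline (0.8 SD) and an AR(1) within-patient component (0.5 SD,
per-hour autocorrelation 0.8, discretized for irregular sampling) — the
minimal structure that makes lookback length matter. Consciousness follows
a sticky Markov chain heavily weighted to alert. Missingness (3% per
variable per observation) and out-of-range erroneous values (0.2%) are
injected and recorded in a ground-truth sidecar, so tests can assert that
cleaning removes exactly the injected corruption.

Deterioration signatures over the final 24 h before the event:

* `level_drift` — progressive shifts toward derangement, peaking at
  SBP −30 mmHg, HR +30 /min, RR +10 /min, BT +1 °C, with consciousness
  worsening probability ramping to 0.2 per observation. These magnitudes
  are typical of the decompensation that precedes arrest or ICU transfer.
* `delta_dominant` — hour-to-hour swings of growing amplitude
  (SBP ±20, HR ±20, RR ±6, BT ±0.8, alternating sign) around an unshifted
  baseline, so the discriminative signal lives almost entirely in
  consecutive differences. This is the regime that motivates the delta
  channels: both variants see the same level sequence, but only V2 receives
  the differences explicitly.
* `none` — labeled cases with no physiologic signature, for null checks.

Event times fall at least onset-lead + lookback hours after admission so
cases always have scoreable windows, and a case's ward stay ends at its
event. What passing tests on these cohorts do **not** show: performance on
real wards, where missingness is informative, charting frequency reacts to
concern, deterioration phenotypes are heterogeneous, and case prevalence
drifts over calendar time.

## Problem sizes in the shipped experiments

The packaged experiments are deliberately desk-scale: the discrimination
and trajectory experiment uses 600 simulated stays (5% events, 2-fold CV,
lookback 24, 8-epoch budget at batch 512); the delta-advantage experiment
uses 250 stays over five paired fold/seed replicates; the acceptance script
reports a 400-stay replicate of the former plus one delta replicate. At
these sizes cross-validated V2 AUROC lands near 0.87–0.89 against a MEWS
baseline near 0.81 — the qualitative ordering, not the magnitudes, is the
reproducible claim, since a few dozen simulated cases cannot pin down
population AUROCs.

## Design choices where the design was open

* Duplicate timestamps keep the last-read row (charting corrections
  overwrite earlier entries), with a warning.
* Temporal splits are half-open: admission exactly at the cutoff goes to
  the test era.
* Direct-ICU and planned-surgery exclusions require admission metadata the
  data model does not carry; they are documented as upstream filters and
  logged as not-applicable. The representable exclusions — no vitals in the
  24 h pre-event, under 30 min of observation — are applied and counted.
* The 2-unit softmax head is kept rather than the mathematically equivalent
  single sigmoid so the risk score remains literally the event-class
  softmax probability.
* Sequences shorter than the lookback are skipped, not padded.

## Known limitations

LSTM/1-D-CNN alternatives, learning-based imputation, sub-hourly grids,
calibration analysis and precision-recall analyses are out of scope. The
simulator's signatures are single-phenotype by design; real deterioration
is heterogeneous. Reported CIs describe simulation uncertainty only.
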