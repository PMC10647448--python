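"""Seeded simulator of general-ward oncology cohorts.

The generator emulates the statistical structure the early-warning method
assumes, so every pipeline stage is testable without access to protected
hospital records: irregular charting at roughly two-hour intervals,
admission vitals centred near SBP 117.3 / HR 86.1 / RR 18.9 / BT 36.6 with
almost-always-alert consciousness, within-patient AR(1) autocorrelation,
~4.5% of stays ending in a deterioration event, and a physiologic signature
unfolding over the final 24 hours before that event.

Two deterioration signatures are available:

``level_drift``
    progressive shift toward derangement — SBP falls, HR and RR rise, BT
    rises, consciousness worsens with increasing probability — the pattern
    a conventional aggregate score can also see;
``delta_dominant``
    hour-to-hour swings grow while the running level stays centred on the
    patient's baseline, so the discriminative signal lives almost entirely
    in consecutive differences — the regime motivating the delta channels.

Ground truth (signature and onset time per stay) is returned in a sidecar
table so tests can assert against what was actually injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AVPU, Cohort, PatientStay, StayOutcome

__all__ = ["SimConfig", "SimulatedStay", "simulate_patient", "simulate_cohort"]

_MINUTE = pd.Timedelta(minutes=1)

#: admission-vital population means and SDs (sbp mmHg, hr /min, rr /min, bt °C)
_BASELINE = {
    "sbp": (117.3, 19.8),
    "hr": (86.1, 19.7),
    "rr": (18.9, 2.8),
    "bt": (36.6, 0.5),
}

#: peak level shifts at the event for the level_drift signature
_DRIFT_MAGNITUDE = {"sbp": -30.0, "hr": 30.0, "rr": 10.0, "bt": 1.0}

#: peak oscillation amplitudes for the delta_dominant signature
_DELTA_AMPLITUDE = {"sbp": 20.0, "hr": 20.0, "rr": 6.0, "bt": 0.8}

#: out-of-range replacements used for erroneous-value injection
_ERROR_VALUES = {"sbp": (500.0, 10.0), "hr": (400.0, 5.0),
                 "rr": (0.0, 80.0), "bt": (50.0, 20.0)}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level generation parameters; defaults emulate the ward cohort.

    ``between_frac``/``within_frac`` split each population SD into a stable
    patient baseline component and an AR(1) within-patient component;
    ``ar_coefficient`` is the per-hour autocorrelation of the latter.
    """

    n_stays: int = 100
    event_prevalence: float = 0.045
    exact_event_count: bool = False
    stay_hours_median: float = 5.7 * 24.0
    stay_log_sd: float = 0.5
    charting_interval_hours: float = 2.0
    charting_jitter_hours: float = 0.5
    baseline: dict = field(default_factory=lambda: dict(_BASELINE))
    alert_probability: float = 0.998
    between_frac: float = 0.8
    within_frac: float = 0.5
    ar_coefficient: float = 0.8
    signature: str = "level_drift"
    onset_lead_hours: float = 24.0
    drift_magnitude: dict = field(default_factory=lambda: dict(_DRIFT_MAGNITUDE))
    delta_amplitude: dict = field(default_factory=lambda: dict(_DELTA_AMPLITUDE))
    consciousness_worsen_peak: float = 0.2
    missing_rate: float = 0.03
    error_rate: float = 0.002
    ihca_fraction: float = 1.77 / (1.77 + 43.45)
    admission_start: str = "2016-01-01"
    admission_end: str = "2020-12-01"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.event_prevalence <= 1.0:
            raise ValueError("event_prevalence must be in [0, 1]")
        if self.signature not in ("level_drift", "delta_dominant", "none"):
            raise ValueError(f"unknown signature {self.signature!r}")
        if self.onset_lead_hours <= 0.5:
            raise ValueError("onset_lead_hours must exceed the 30 min near bound")
        for name, (_, sd) in self.baseline.items():
            if sd <= 0:
                raise ValueError(f"{name}: SD must be positive")


@dataclass
class SimulatedStay:
    """A generated stay plus the ground truth behind it."""

    stay: PatientStay
    signature: str  # signature actually applied ("none" for controls)
    onset_time: pd.Timestamp | None
    n_injected_errors: int


def _charting_offsets(rng: np.random.Generator, total_hours: float,
                      cfg: SimConfig) -> np.ndarray:
    """Observation times in hours from admission, first one at admission."""
    times = [0.0]
    t = 0.0
    while True:
        gap = rng.normal(cfg.charting_interval_hours, cfg.charting_jitter_hours)
        t += float(np.clip(gap, 0.25, 6.0))
        if t >= total_hours:
            break
        times.append(t)
    return np.asarray(times)


def _latent_series(rng: np.random.Generator, n: int, dt: np.ndarray,
                   mean: float, sd: float, cfg: SimConfig) -> np.ndarray:
    """Baseline + irregular-sampling AR(1) noise for one variable."""
    baseline = rng.normal(mean, cfg.between_frac * sd)
    sigma_w = cfg.within_frac * sd
    x = np.empty(n)
    x[0] = baseline + rng.normal(0.0, sigma_w)
    for j in range(1, n):
        phi = cfg.ar_coefficient ** dt[j]
        innov_sd = sigma_w * np.sqrt(max(1.0 - phi * phi, 1e-12))
        x[j] = baseline + phi * (x[j - 1] - baseline) + rng.normal(0.0, innov_sd)
    return x


def simulate_patient(
    config: SimConfig,
    patient_id: str,
    deteriorated: bool,
    admission_time: pd.Timestamp,
    rng: np.random.Generator,
) -> SimulatedStay:
    """Generate one stay; the observable part is a valid :class:`PatientStay`."""
    lead = config.onset_lead_hours
    total_hours = float(
        np.exp(rng.normal(np.log(config.stay_hours_median), config.stay_log_sd))
    )
    total_hours = float(np.clip(total_hours, 6.0, 2400.0))
    event_offset = None
    if deteriorated:
        # event at least onset-lead + lookback after admission so cases
        # always have scoreable windows; the ward stay ends at the event
        min_offset = lead + 26.0
        total_hours = max(total_hours, min_offset + 2.0)
        event_offset = rng.uniform(min_offset, total_hours)
        total_hours = event_offset

    offsets = _charting_offsets(rng, total_hours, config)
    n = len(offsets)
    dt = np.diff(offsets, prepend=offsets[0])

    sig = config.signature if deteriorated else "none"
    progress = np.zeros(n)
    if deteriorated and sig != "none":
        tte = event_offset - offsets  # hours to event, > 0
        progress = np.clip(1.0 - tte / lead, 0.0, 1.0)

    values: dict[str, np.ndarray] = {}
    flip = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    for var, (mean, sd) in config.baseline.items():
        x = _latent_series(rng, n, dt, mean, sd, config)
        if sig == "level_drift":
            x = x + config.drift_magnitude[var] * progress
        elif sig == "delta_dominant":
            x = x + flip * config.delta_amplitude[var] * progress
        values[var] = x

    # consciousness: sticky Markov chain heavily weighted to alert
    q0 = 1.0 - config.alert_probability
    worsen_peak = config.consciousness_worsen_peak if sig == "level_drift" else 0.0
    state = 0
    cs = np.empty(n)
    for j in range(n):
        q = q0 + worsen_peak * progress[j] ** 2
        if state > 0 and rng.random() < 0.3:
            state -= 1
        if rng.random() < q:
            state = min(state + 1, 3)
        cs[j] = float(state)
    values["consciousness"] = cs

    # physiological rounding to charting precision
    for var in ("sbp", "hr", "rr"):
        values[var] = np.round(values[var])
    values["bt"] = np.round(values["bt"], 1)

    # missingness (admission vitals always fully charted)
    for var in ("sbp", "hr", "rr", "bt", "consciousness"):
        miss = rng.random(n) < config.missing_rate
        miss[0] = False
        values[var][miss] = np.nan

    # erroneous out-of-range injections
    n_errors = 0
    for var in ("sbp", "hr", "rr", "bt"):
        bad = (rng.random(n) < config.error_rate) & np.isfinite(values[var])
        for j in np.flatnonzero(bad):
            values[var][j] = _ERROR_VALUES[var][int(rng.integers(2))]
            n_errors += 1

    timestamps = admission_time + pd.to_timedelta(
        np.round(offsets * 60.0), unit="m"
    )
    if deteriorated:
        event_time = admission_time + pd.Timedelta(
            minutes=float(np.ceil(event_offset * 60.0))
        )
        discharge = event_time
        event_type = "IHCA" if rng.random() < config.ihca_fraction else "ICU"
        outcome = StayOutcome(True, event_time, event_type)
        onset = event_time - pd.Timedelta(hours=lead)
    else:
        discharge = admission_time + pd.Timedelta(
            minutes=float(np.ceil(total_hours * 60.0))
        )
        outcome = StayOutcome(False)
        onset = None

    obs = pd.DataFrame(
        {
            "timestamp": timestamps,
            "sbp": values["sbp"],
            "hr": values["hr"],
            "rr": values["rr"],
            "bt": values["bt"],
            "consciousness": values["consciousness"],
        }
    )
    stay = PatientStay(
        patient_id=patient_id,
        admission_time=admission_time,
        discharge_time=discharge,
        observations=obs,
        outcome=outcome,
    )
    return SimulatedStay(stay, sig, onset, n_errors)


def simulate_cohort(config: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort and its ground-truth sidecar; deterministic per seed.

    In ``exact_event_count`` mode exactly round(n × prevalence) stays
    deteriorate; otherwise each stay deteriorates independently with the
    configured prevalence.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_stays
    if config.exact_event_count:
        k = int(round(n * config.event_prevalence))
        flags = np.zeros(n, dtype=bool)
        flags[rng.choice(n, size=k, replace=False)] = True
    else:
        flags = rng.random(n) < config.event_prevalence

    start = pd.Timestamp(config.admission_start)
    end = pd.Timestamp(config.admission_end)
    span_minutes = int((end - start) / _MINUTE)
    admissions = start + pd.to_timedelta(
        rng.integers(0, span_minutes, size=n), unit="m"
    )

    width = len(str(n - 1))
    sims = [
        simulate_patient(config, f"P{i:0{width}d}", bool(flags[i]),
                         admissions[i], rng)
        for i in range(n)
    ]
    cohort = Cohort(
        [s.stay for s in sims],
        metadata={
            "source": "canews.synth",
            "seed": config.seed,
            "signature": config.signature,
            "n_stays": n,
        },
    )
    truth = pd.DataFrame(
        {
            "patient_id": [s.stay.patient_id for s in sims],
            "signature": [s.signature for s in sims],
            "onset_time": [s.onset_time for s in sims],
            "event_time": [
                s.stay.outcome.event_time if s.stay.outcome.deteriorated else None
                for s in sims
            ],
            "n_injected_errors": [s.n_injected_errors for s in sims],
        }
    )
    return cohort, truth
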