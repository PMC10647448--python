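"""Ward-cohort data model, CSV readers/writers, validation, and partitioning.

A cohort is a collection of hospital stays.  Each stay carries a time-ordered
series of charted vital-sign observations (systolic blood pressure, heart
rate, respiratory rate, body temperature, AVPU consciousness) and an outcome
record stating whether the stay ended in clinical deterioration — the
composite of in-hospital cardiac arrest (IHCA) and unexpected ICU transfer —
and, if so, when.

On-disk format is two long CSV files:

observations:  patient_id, timestamp (ISO-8601), sbp, hr, rr, bt, consciousness
outcomes:      patient_id, admission_time, discharge_time, deteriorated (0/1),
               event_time, event_type (IHCA/ICU)

Empty cells denote missing values.  An optional ``dbp`` column is accepted in
observation files for cleaning compatibility but is never used by any model.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "AVPU",
    "StayOutcome",
    "PatientStay",
    "Cohort",
    "SchemaError",
    "CohortValidationError",
    "EVENT_TYPES",
    "VITAL_COLUMNS",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
    "split_temporal",
    "split_stratified_kfold",
]

#: the five charted variables, in canonical feature order
VITAL_COLUMNS = ["sbp", "hr", "rr", "bt", "consciousness"]
NUMERIC_VITALS = ["sbp", "hr", "rr", "bt"]

OBS_COLUMNS = ["patient_id", "timestamp", *VITAL_COLUMNS]
OUTCOME_COLUMNS = [
    "patient_id",
    "admission_time",
    "discharge_time",
    "deteriorated",
    "event_time",
    "event_type",
]

EVENT_TYPES = ("IHCA", "ICU")

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S"


class SchemaError(ValueError):
    """A CSV file does not match the documented column schema."""


class CohortValidationError(ValueError):
    """A stay or outcome record violates a data-model invariant."""


class AVPU(enum.IntEnum):
    """Level of consciousness on the AVPU scale.

    Ordered from fully alert to unresponsive; the integer value is the
    ordinal encoding fed to models (A=0 … U=3).
    """

    A = 0  # alert
    V = 1  # responds to voice
    P = 2  # responds to pain
    U = 3  # unresponsive

    @classmethod
    def from_string(cls, s: str) -> "AVPU":
        try:
            return cls[s.strip().upper()]
        except KeyError:
            raise ValueError(f"not an AVPU level: {s!r}") from None


@dataclass
class StayOutcome:
    """Outcome of one stay; only the first deterioration event is recorded."""

    deteriorated: bool
    event_time: pd.Timestamp | None = None
    event_type: str | None = None

    def __post_init__(self) -> None:
        if self.deteriorated:
            if self.event_time is None:
                raise CohortValidationError("deteriorated stay lacks event_time")
            if self.event_type not in EVENT_TYPES:
                raise CohortValidationError(
                    f"event_type must be one of {EVENT_TYPES}, got {self.event_type!r}"
                )
        else:
            self.event_time = None
            self.event_type = None


@dataclass
class PatientStay:
    """One hospital stay: charted observations plus the outcome record.

    ``observations`` is a DataFrame with columns ``timestamp`` (datetime64,
    strictly increasing), the four numeric vitals (float, NaN = missing) and
    ``consciousness`` (float ordinal 0–3 per :class:`AVPU`, NaN = missing).
    """

    patient_id: str
    admission_time: pd.Timestamp
    discharge_time: pd.Timestamp
    observations: pd.DataFrame
    outcome: StayOutcome

    def __post_init__(self) -> None:
        if self.admission_time >= self.discharge_time:
            raise CohortValidationError(
                f"{self.patient_id}: admission_time must precede discharge_time"
            )
        if len(self.observations) == 0:
            raise CohortValidationError(f"{self.patient_id}: stay has no observations")
        ts = self.observations["timestamp"]
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise CohortValidationError(
                f"{self.patient_id}: observation timestamps must be strictly increasing"
            )
        if (ts < self.admission_time).any() or (ts > self.discharge_time).any():
            raise CohortValidationError(
                f"{self.patient_id}: observation outside admission–discharge interval"
            )
        out = self.outcome
        if out.deteriorated:
            if not (self.admission_time < out.event_time <= self.discharge_time):
                raise CohortValidationError(
                    f"{self.patient_id}: event_time outside (admission, discharge]"
                )

    @property
    def span(self) -> pd.Timedelta:
        ts = self.observations["timestamp"]
        return ts.iloc[-1] - ts.iloc[0]


@dataclass
class Cohort:
    """A list of stays with unique patient ids plus free-form provenance."""

    stays: list[PatientStay]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.patient_id for s in self.stays]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("patient_id not unique across stays")

    def __len__(self) -> int:
        return len(self.stays)

    def __iter__(self):
        return iter(self.stays)

    @property
    def n_events(self) -> int:
        return sum(s.outcome.deteriorated for s in self.stays)

    @property
    def patient_ids(self) -> list[str]:
        return [s.patient_id for s in self.stays]

    def subset(self, ids) -> "Cohort":
        wanted = set(ids)
        return Cohort(
            [s for s in self.stays if s.patient_id in wanted], dict(self.metadata)
        )


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} file is missing required column {col!r}")


def _parse_consciousness(series: pd.Series) -> pd.Series:
    """Map A/V/P/U strings to ordinals; anything else becomes missing."""
    mapping = {lvl.name: float(lvl.value) for lvl in AVPU}

    def conv(x):
        if isinstance(x, str):
            return mapping.get(x.strip().upper(), np.nan)
        return np.nan

    return series.map(conv).astype(float)


def read_cohort(observations_path, outcomes_path) -> Cohort:
    """Read a cohort from the two-file CSV layout.

    Non-numeric entries in numeric vital columns become missing values rather
    than errors.  Duplicate timestamps within a stay keep the last-read row
    (charting corrections overwrite earlier entries) with a warning.
    """
    obs = pd.read_csv(observations_path, dtype={"patient_id": str})
    out = pd.read_csv(outcomes_path, dtype={"patient_id": str})
    _require_columns(obs, OBS_COLUMNS, "observations")
    _require_columns(out, OUTCOME_COLUMNS, "outcomes")

    obs = obs.copy()
    obs["timestamp"] = pd.to_datetime(obs["timestamp"])
    numeric_cols = NUMERIC_VITALS + (["dbp"] if "dbp" in obs.columns else [])
    for col in numeric_cols:
        obs[col] = pd.to_numeric(obs[col], errors="coerce")
    obs["consciousness"] = _parse_consciousness(obs["consciousness"])
    keep_cols = OBS_COLUMNS + (["dbp"] if "dbp" in obs.columns else [])
    obs = obs[keep_cols]

    for col in ("admission_time", "discharge_time", "event_time"):
        out[col] = pd.to_datetime(out[col])

    grouped = {pid: g for pid, g in obs.groupby("patient_id", sort=False)}
    stays: list[PatientStay] = []
    for row in out.itertuples(index=False):
        pid = row.patient_id
        deteriorated = bool(int(row.deteriorated))
        if deteriorated and pd.isna(row.event_time):
            raise CohortValidationError(
                f"{pid}: deteriorated=1 but event_time is missing"
            )
        outcome = StayOutcome(
            deteriorated=deteriorated,
            event_time=row.event_time if deteriorated else None,
            event_type=row.event_type if deteriorated else None,
        )
        g = grouped.get(pid)
        if g is None:
            raise CohortValidationError(f"{pid}: outcome record with no observations")
        g = g.sort_values("timestamp", kind="stable")
        dup = g["timestamp"].duplicated(keep="last")
        if dup.any():
            warnings.warn(
                f"{pid}: {int(dup.sum())} duplicate timestamps; keeping last-read rows",
                stacklevel=2,
            )
            g = g[~dup]
        stays.append(
            PatientStay(
                patient_id=pid,
                admission_time=row.admission_time,
                discharge_time=row.discharge_time,
                observations=g.drop(columns="patient_id").reset_index(drop=True),
                outcome=outcome,
            )
        )
    return Cohort(stays, metadata={"source": str(observations_path)})


def _consciousness_to_letter(x: float) -> str:
    return "" if pd.isna(x) else AVPU(int(x)).name


def write_cohort(cohort: Cohort, observations_path, outcomes_path) -> None:
    """Write a cohort back to the two-file CSV layout (read round-trips)."""
    obs_frames = []
    out_rows = []
    for stay in cohort:
        g = stay.observations.copy()
        g.insert(0, "patient_id", stay.patient_id)
        g["timestamp"] = g["timestamp"].dt.strftime(_TS_FORMAT)
        g["consciousness"] = g["consciousness"].map(_consciousness_to_letter)
        cols = OBS_COLUMNS + (["dbp"] if "dbp" in g.columns else [])
        obs_frames.append(g[cols])
        o = stay.outcome
        out_rows.append(
            {
                "patient_id": stay.patient_id,
                "admission_time": stay.admission_time.strftime(_TS_FORMAT),
                "discharge_time": stay.discharge_time.strftime(_TS_FORMAT),
                "deteriorated": int(o.deteriorated),
                "event_time": o.event_time.strftime(_TS_FORMAT) if o.deteriorated else "",
                "event_type": o.event_type if o.deteriorated else "",
            }
        )
    pd.concat(obs_frames, ignore_index=True).to_csv(observations_path, index=False)
    pd.DataFrame(out_rows, columns=OUTCOME_COLUMNS).to_csv(outcomes_path, index=False)


def apply_exclusions(
    cohort: Cohort, pre_event_window: pd.Timedelta = pd.Timedelta(hours=24),
    min_span: pd.Timedelta = pd.Timedelta(minutes=30),
) -> tuple[Cohort, dict]:
    """Drop stays unusable for event prediction; return the survivors and a log.

    Removed are (a) deteriorated stays with no observation inside the 24 h
    before the event and (b) stays whose total observation span is under
    30 min.  Direct-ICU admissions and planned-surgery admissions are upstream
    filters on admission metadata this data model does not carry; the log
    marks them not applicable.
    """
    kept: list[PatientStay] = []
    log = {
        "no_vitals_24h_pre_event": 0,
        "span_under_30min": 0,
        "direct_icu_admission": "not applicable (upstream filter)",
        "planned_surgery": "not applicable (upstream filter)",
    }
    for stay in cohort:
        ts = stay.observations["timestamp"]
        if stay.outcome.deteriorated:
            ev = stay.outcome.event_time
            in_window = (ts >= ev - pre_event_window) & (ts <= ev)
            if not in_window.any():
                log["no_vitals_24h_pre_event"] += 1
                continue
        if stay.span < min_span:
            log["span_under_30min"] += 1
            continue
        kept.append(stay)
    return Cohort(kept, dict(cohort.metadata)), log


def split_temporal(cohort: Cohort, cutoff: pd.Timestamp) -> tuple[Cohort, Cohort]:
    """Partition stays by admission time: before the cutoff → train, at or
    after → test (half-open [start, cutoff) convention for the training era)."""
    train = [s for s in cohort if s.admission_time < cutoff]
    test = [s for s in cohort if s.admission_time >= cutoff]
    meta = dict(cohort.metadata)
    return Cohort(train, meta), Cohort(test, dict(meta))


def split_stratified_kfold(
    cohort: Cohort, k: int, seed: int
) -> list[tuple[Cohort, Cohort]]:
    """Stay-level stratified k-fold split on the deterioration outcome.

    Stratifying at the stay level keeps all of a patient's observation
    windows on one side of each fold, preventing within-patient leakage.
    Deterministic for a given seed.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    labels = np.array([int(s.outcome.deteriorated) for s in cohort.stays])
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos < k or n_neg < k:
        raise ValueError(
            f"need at least k={k} stays per class, have {n_pos} deteriorated "
            f"and {n_neg} non-deteriorated"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    ids = np.array(cohort.patient_ids)
    folds = []
    for train_idx, val_idx in skf.split(ids, labels):
        folds.append((cohort.subset(ids[train_idx]), cohort.subset(ids[val_idx])))
    return folds
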