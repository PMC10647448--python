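"""Cleaning, hourly resampling, delta features, and event-window labeling.

The pipeline turns a :class:`~canews.cohort.PatientStay` into model-ready
lookback windows:

1. range cleaning — physiologically impossible values become missing;
2. hourly resampling — one resolved value per variable per whole hour, using
   the charted value closest to (i.e. most recent at or before) the grid
   point, carrying the last value forward across gaps;
3. delta channels — consecutive hourly differences of each variable;
4. sliding lookback windows with binary labels: a window is positive when
   its reference hour falls between 30 minutes and 24 hours before the
   stay's deterioration event.

Coordinate convention: the grid starts at the first observation's timestamp
truncated to the whole hour and steps by exactly one hour up to
min(discharge, event time).  A window's reference time is the grid hour
being scored; its feature rows run oldest → newest and contain only
information charted at or before the reference time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import NUMERIC_VITALS, VITAL_COLUMNS, PatientStay, StayOutcome

__all__ = [
    "CleaningRanges",
    "EventWindowSpec",
    "HourlyGrid",
    "FeatureWindow",
    "PHYSIOLOGIC_DEFAULTS",
    "DELTA_COLUMNS",
    "clean_observations",
    "encode_consciousness",
    "resample_hourly",
    "compute_deltas",
    "label_hour",
    "build_feature_windows",
    "stack_windows",
]

DELTA_COLUMNS = [f"d_{c}" for c in VITAL_COLUMNS]

#: substitutes for a variable never charted during a stay
PHYSIOLOGIC_DEFAULTS = {
    "sbp": 120.0,
    "hr": 80.0,
    "rr": 18.0,
    "bt": 36.5,
    "consciousness": 0.0,  # alert
}


@dataclass(frozen=True)
class CleaningRanges:
    """Closed acceptance intervals; values outside become missing.

    Defaults are the conventional charting plausibility limits: SBP 30–300
    mmHg, HR 10–300 /min, RR 3–60 /min, BT 30–45 °C, plus a DBP pass-through
    range (40–120 mmHg) for files that carry a dbp column.
    """

    sbp: tuple[float, float] = (30.0, 300.0)
    hr: tuple[float, float] = (10.0, 300.0)
    rr: tuple[float, float] = (3.0, 60.0)
    bt: tuple[float, float] = (30.0, 45.0)
    dbp: tuple[float, float] = (40.0, 120.0)

    def __post_init__(self):
        for name in ("sbp", "hr", "rr", "bt", "dbp"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be below upper bound")

    def interval(self, variable: str) -> tuple[float, float]:
        return getattr(self, variable)


@dataclass(frozen=True)
class EventWindowSpec:
    """Labeling interval before the event: [far_bound, near_bound] pre-event.

    Hours closer to the event than ``near_bound`` (default 30 min) are a
    blackout — too late to act on — and are excluded from windowing for
    deteriorated stays; hours further back than ``far_bound`` (default 24 h)
    are labeled negative.
    """

    near_bound: pd.Timedelta = pd.Timedelta(minutes=30)
    far_bound: pd.Timedelta = pd.Timedelta(hours=24)

    def __post_init__(self):
        if not self.near_bound < self.far_bound:
            raise ValueError("near_bound must be smaller than far_bound")


@dataclass
class HourlyGrid:
    """Resolved hourly values for one stay.

    ``values`` has one row per grid hour and columns for the five variables
    (consciousness as ordinal 0–3) plus, after :func:`compute_deltas`, the
    five ``d_*`` difference channels.  No missing entries remain.
    """

    patient_id: str
    times: pd.DatetimeIndex
    values: pd.DataFrame

    def __len__(self) -> int:
        return len(self.times)

    @property
    def has_deltas(self) -> bool:
        return all(c in self.values.columns for c in DELTA_COLUMNS)


@dataclass
class FeatureWindow:
    """One scored lookback window: an L×F feature matrix plus its label."""

    patient_id: str
    reference_time: pd.Timestamp
    features: np.ndarray  # (lookback, 5 or 10), rows oldest → newest
    label: int

    def __post_init__(self):
        if self.features.ndim != 2 or self.features.shape[1] not in (5, 10):
            raise ValueError("features must be L×5 or L×10")
        if not np.isfinite(self.features).all():
            raise ValueError("features must be finite")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def clean_observations(
    stay: PatientStay, ranges: CleaningRanges | None = None
) -> tuple[PatientStay, dict]:
    """Replace out-of-range numeric vitals with missing; count per variable.

    Consciousness is categorical and untouched.  Idempotent: cleaning a
    cleaned stay changes nothing.
    """
    ranges = ranges or CleaningRanges()
    obs = stay.observations.copy()
    log: dict[str, int] = {}
    for col in NUMERIC_VITALS:
        lo, hi = ranges.interval(col)
        bad = obs[col].notna() & ((obs[col] < lo) | (obs[col] > hi))
        log[col] = int(bad.sum())
        obs.loc[bad, col] = np.nan
    if "dbp" in obs.columns:
        lo, hi = ranges.interval("dbp")
        bad = obs["dbp"].notna() & ((obs["dbp"] < lo) | (obs["dbp"] > hi))
        log["dbp"] = int(bad.sum())
        obs.loc[bad, "dbp"] = np.nan
    return replace(stay, observations=obs), log


def encode_consciousness(level) -> float:
    """Ordinal encoding of the AVPU scale: A→0, V→1, P→2, U→3."""
    from .cohort import AVPU

    if isinstance(level, str):
        level = AVPU.from_string(level)
    return float(int(level))


def resample_hourly(
    stay: PatientStay,
    ranges: CleaningRanges | None = None,
    defaults: dict | None = None,
) -> HourlyGrid:
    """Resolve each variable onto the stay's whole-hour grid.

    For each grid hour the resolved value is the charted value closest in
    time at or before the grid point — i.e. the most recent value, carried
    forward across charting gaps.  Hours before a variable's first
    measurement are back-filled from that first value; a variable never
    measured in the stay takes a configured physiologic default with a
    warning.  The stay is range-cleaned first.
    """
    if len(stay.observations) == 0:
        raise ValueError(f"{stay.patient_id}: cannot resample a stay with no observations")
    stay, _ = clean_observations(stay, ranges)
    defaults = defaults or PHYSIOLOGIC_DEFAULTS

    obs = stay.observations
    start = obs["timestamp"].iloc[0].floor("h")
    end = stay.discharge_time
    if stay.outcome.deteriorated:
        end = min(end, stay.outcome.event_time)
    times = pd.date_range(start, end, freq="1h")

    obs_ts = obs["timestamp"].to_numpy()
    grid_ts = times.to_numpy()
    resolved = {}
    for col in VITAL_COLUMNS:
        vals = obs[col].to_numpy(dtype=float)
        mask = np.isfinite(vals)
        if not mask.any():
            warnings.warn(
                f"{stay.patient_id}: {col} never measured; using default "
                f"{defaults[col]}",
                stacklevel=2,
            )
            resolved[col] = np.full(len(times), float(defaults[col]))
            continue
        vt, vv = obs_ts[mask], vals[mask]
        # index of last charted value at or before each grid point
        idx = np.searchsorted(vt, grid_ts, side="right") - 1
        lead = idx < 0  # grid hours before the first measurement
        out = vv[np.clip(idx, 0, None)]
        out[lead] = vv[0]
        resolved[col] = out
    return HourlyGrid(stay.patient_id, times, pd.DataFrame(resolved, index=times))


def compute_deltas(grid: HourlyGrid) -> HourlyGrid:
    """Append hour-to-hour difference channels; the first hour's delta is 0.

    Consciousness deltas are differences of the ordinal encoding.  The zero
    at the sequence start keeps every window's shape fixed; summing deltas
    telescopes back to last − first value.
    """
    values = grid.values.copy()
    for col in VITAL_COLUMNS:
        d = values[col].diff()
        d.iloc[0] = 0.0
        values[f"d_{col}"] = d
    return HourlyGrid(grid.patient_id, grid.times, values)


def label_hour(
    reference_time: pd.Timestamp,
    outcome: StayOutcome,
    spec: EventWindowSpec | None = None,
) -> int:
    """1 iff the hour falls in the pre-event labeling interval, else 0."""
    spec = spec or EventWindowSpec()
    if not outcome.deteriorated:
        return 0
    ev = outcome.event_time
    return int(ev - spec.far_bound <= reference_time <= ev - spec.near_bound)


def build_feature_windows(
    grid: HourlyGrid,
    outcome: StayOutcome,
    lookback: int = 24,
    variant: str = "V2",
    spec: EventWindowSpec | None = None,
) -> list[FeatureWindow]:
    """Slide a lookback window over the grid, one window per eligible hour.

    Windows start at grid index lookback−1 (the first hour with a full
    history).  For deteriorated stays, hours inside the near-bound blackout
    before the event are not emitted at all; the grid itself ends at the
    event, so no window ever sees post-event data.  A grid shorter than the
    lookback yields an empty list.
    """
    spec = spec or EventWindowSpec()
    if lookback < 1:
        raise ValueError("lookback must be at least 1")
    if variant not in ("V1", "V2"):
        raise ValueError("variant must be 'V1' or 'V2'")
    if variant == "V2" and not grid.has_deltas:
        grid = compute_deltas(grid)
    cols = VITAL_COLUMNS if variant == "V1" else VITAL_COLUMNS + DELTA_COLUMNS
    if len(grid) < lookback:
        return []
    mat = grid.values[cols].to_numpy(dtype=float)
    windows: list[FeatureWindow] = []
    for i in range(lookback - 1, len(grid)):
        ref = grid.times[i]
        if outcome.deteriorated:
            if ref > outcome.event_time - spec.near_bound:
                continue  # blackout: too close to (or past) the event
        windows.append(
            FeatureWindow(
                patient_id=grid.patient_id,
                reference_time=ref,
                features=mat[i - lookback + 1 : i + 1],
                label=label_hour(ref, outcome, spec),
            )
        )
    return windows


def stack_windows(
    windows: list[FeatureWindow],
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Stack windows into (X, y, index) arrays for training and scoring.

    X is (n, L, F); the index frame carries patient_id and reference_time
    aligned with the rows of X.
    """
    if not windows:
        raise ValueError("no windows to stack")
    X = np.stack([w.features for w in windows])
    y = np.array([w.label for w in windows], dtype=int)
    index = pd.DataFrame(
        {
            "patient_id": [w.patient_id for w in windows],
            "reference_time": [w.reference_time for w in windows],
        }
    )
    return X, y, index
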