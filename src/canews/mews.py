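"""Configurable banded scoring engine for the Modified Early Warning Score.

MEWS assigns 0–3 points to each of five routine vitals — systolic blood
pressure, heart rate, respiratory rate, body temperature and AVPU
consciousness — by banded cut-offs and sums them.  The engine is
table-agnostic: the packaged default table ships as an editable YAML config
(see ``data/mews_default.yaml`` for its provenance) and users can substitute
local variants, including NEWS-style tables, through the same mechanism.

Numeric bands are closed-below/open-above and must partition the real line
per variable; consciousness bands are keyed by AVPU level.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .cohort import AVPU, VITAL_COLUMNS
from .preprocessing import HourlyGrid

__all__ = [
    "ScoringBand",
    "ScoringTable",
    "ScoringTableError",
    "load_scoring_table",
    "mews_score",
    "mews_series",
]

NUMERIC_VARIABLES = ["sbp", "hr", "rr", "bt"]


class ScoringTableError(ValueError):
    """A scoring table fails validation (gap, overlap, missing variable)."""


@dataclass(frozen=True)
class ScoringBand:
    """One half-open interval [lo, hi) worth a fixed number of points."""

    variable: str
    lo: float
    hi: float
    points: int

    def __post_init__(self):
        if self.points not in (0, 1, 2, 3):
            raise ScoringTableError(
                f"{self.variable}: points must be 0–3, got {self.points}"
            )
        if not self.lo < self.hi:
            raise ScoringTableError(
                f"{self.variable}: empty band [{self.lo}, {self.hi})"
            )


@dataclass(frozen=True)
class ScoringTable:
    """Validated per-variable bands covering the four numeric vitals and AVPU.

    ``numeric`` maps variable → bands sorted by lo, partitioning (−inf, +inf);
    ``consciousness`` maps each AVPU level to its points.
    """

    numeric: dict[str, tuple[ScoringBand, ...]]
    consciousness: dict[AVPU, int]

    def __post_init__(self):
        for var in NUMERIC_VARIABLES:
            bands = self.numeric.get(var)
            if not bands:
                raise ScoringTableError(f"no bands defined for {var!r}")
            bands = tuple(sorted(bands, key=lambda b: b.lo))
            if bands[0].lo != -np.inf or bands[-1].hi != np.inf:
                raise ScoringTableError(f"{var}: bands must span -inf to +inf")
            for a, b in zip(bands, bands[1:]):
                if a.hi < b.lo:
                    raise ScoringTableError(
                        f"{var}: gap between {a.hi} and {b.lo}"
                    )
                if a.hi > b.lo:
                    raise ScoringTableError(
                        f"{var}: bands [{a.lo},{a.hi}) and [{b.lo},{b.hi}) overlap"
                    )
            object.__setattr__(
                self, "numeric", {**self.numeric, var: bands}
            )
        if set(self.consciousness) != set(AVPU):
            raise ScoringTableError("consciousness bands must cover all AVPU levels")
        for lvl, pts in self.consciousness.items():
            if pts not in (0, 1, 2, 3):
                raise ScoringTableError(f"consciousness {lvl.name}: points must be 0–3")

    def points_for(self, variable: str, value: float) -> int:
        if variable == "consciousness":
            return self.consciousness[AVPU(int(value))]
        for band in self.numeric[variable]:
            if band.lo <= value < band.hi:
                return band.points
        raise AssertionError("partition invariant violated")  # pragma: no cover

    def max_score(self) -> int:
        per_var = [max(b.points for b in self.numeric[v]) for v in NUMERIC_VARIABLES]
        return sum(per_var) + max(self.consciousness.values())

    def _edges_points(self, variable: str) -> tuple[np.ndarray, np.ndarray]:
        bands = self.numeric[variable]
        edges = np.array([b.lo for b in bands[1:]])
        points = np.array([b.points for b in bands])
        return edges, points


def load_scoring_table(source: str = "default") -> ScoringTable:
    """Load and validate a scoring table from YAML ("default" = packaged MEWS)."""
    if source == "default":
        text = (
            resources.files("canews").joinpath("data/mews_default.yaml").read_text()
        )
        raw = yaml.safe_load(text)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    numeric: dict[str, tuple[ScoringBand, ...]] = {}
    for var in NUMERIC_VARIABLES:
        entries = raw.get(var)
        if not entries:
            raise ScoringTableError(f"scoring table missing bands for {var!r}")
        numeric[var] = tuple(
            ScoringBand(
                variable=var,
                lo=float(e.get("lo", -np.inf)),
                hi=float(e.get("hi", np.inf)),
                points=int(e["points"]),
            )
            for e in entries
        )
    cs_raw = raw.get("consciousness")
    if not cs_raw:
        raise ScoringTableError("scoring table missing consciousness bands")
    consciousness = {AVPU[k.upper()]: int(v) for k, v in cs_raw.items()}
    return ScoringTable(numeric=numeric, consciousness=consciousness)


def mews_score(vitals: dict, table: ScoringTable) -> int:
    """Score one resolved 5-variable vector; all five values must be present.

    ``vitals`` maps sbp/hr/rr/bt to numbers and consciousness to an AVPU
    level, its letter, or the 0–3 ordinal.  The total is the sum of the five
    matched band points (0–14 with the packaged default table).
    """
    total = 0
    for var in VITAL_COLUMNS:
        if var not in vitals or vitals[var] is None:
            raise ValueError(f"missing value for {var!r}; impute before scoring")
        value = vitals[var]
        if var == "consciousness" and isinstance(value, str):
            value = AVPU.from_string(value)
        value = float(value)
        if np.isnan(value):
            raise ValueError(f"missing value for {var!r}; impute before scoring")
        total += table.points_for(var, value)
    return total


def mews_series(grid: HourlyGrid, table: ScoringTable) -> np.ndarray:
    """Hourly MEWS over an imputed grid; one integer score per grid hour."""
    n = len(grid)
    total = np.zeros(n, dtype=int)
    for var in NUMERIC_VARIABLES:
        edges, points = table._edges_points(var)
        idx = np.searchsorted(edges, grid.values[var].to_numpy(), side="right")
        total += points[idx]
    cs_points = np.array([table.consciousness[AVPU(i)] for i in range(4)])
    cs = grid.values["consciousness"].to_numpy().astype(int)
    total += cs_points[np.clip(cs, 0, 3)]
    return total
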