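"""Evaluation protocol: discrimination, alarm burden, and trajectories.

Scores are evaluated at the level of scored observations.  A deteriorated
stay contributes the hours from 24 h to 30 min before its event, labeled
positive; a non-deteriorated stay contributes either every serial hour
(``serial`` mode) or a single per-patient maximum (``per_patient_max``
mode, the conventional rule for aggregate scores such as MEWS).

Provided statistics:

* AUROC (Mann–Whitney, ties counted 1/2) with a patient-level stratified
  bootstrap 95% CI;
* a paired correlated-AUROC z-test for comparing two scores on identical
  observations (placement-value covariance estimator);
* per-threshold confusion metrics, matched-sensitivity thresholds, and
  false alarms per day of control observation — the alarm-fatigue burden;
* stay-level stratified cross-validation of the recurrent models with a
  MEWS column computed on the very same observation set;
* the lookback sweep and the mean pre-event risk trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort import Cohort, PatientStay, split_stratified_kfold
from .mews import ScoringTable, load_scoring_table, mews_series
from .model import CanEWSModel, ModelConfig, RiskSeries, build_model, predict_risk, train
from .preprocessing import (
    CleaningRanges,
    EventWindowSpec,
    build_feature_windows,
    compute_deltas,
    resample_hourly,
    stack_windows,
)

__all__ = [
    "OperatingPoint",
    "AUROCResult",
    "ComparisonResult",
    "EvalReport",
    "collect_scored_observations",
    "roc_auc",
    "compare_auroc",
    "confusion_at_threshold",
    "threshold_for_sensitivity",
    "false_alarms_per_day",
    "matched_sensitivity_table",
    "cross_validate",
    "lookback_sweep",
    "risk_trajectory",
]

OBS_COLUMNS = ["patient_id", "reference_time", "score", "label"]


@dataclass(frozen=True)
class OperatingPoint:
    """One row of a threshold table: alarm when score >= threshold."""

    score_name: str
    threshold: float
    sensitivity: float  # %
    specificity: float  # %
    ppv: float  # %
    npv: float  # %
    false_alarms_per_day: float | None = None

    def __post_init__(self):
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            if np.isfinite(v) and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100]")
        if self.false_alarms_per_day is not None and self.false_alarms_per_day < 0:
            raise ValueError("false_alarms_per_day must be non-negative")


@dataclass(frozen=True)
class AUROCResult:
    auroc: float
    ci_lower: float
    ci_upper: float
    n_positive: int
    n_negative: int

    def __post_init__(self):
        if not self.ci_lower <= self.auroc <= self.ci_upper:
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class ComparisonResult:
    auroc_a: float
    auroc_b: float
    z: float
    p_value: float
    method: str = "paired correlated-AUROC z-test (placement-value covariance)"


@dataclass
class EvalReport:
    """Aggregated evaluation output for one observation set."""

    auroc: dict[str, AUROCResult]
    operating_points: list[OperatingPoint] = field(default_factory=list)
    comparisons: dict[str, ComparisonResult] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auroc": {
                k: {"auroc": v.auroc, "ci": [v.ci_lower, v.ci_upper],
                    "n_positive": v.n_positive, "n_negative": v.n_negative}
                for k, v in self.auroc.items()
            },
            "operating_points": [vars(op) for op in self.operating_points],
            "comparisons": {
                k: {"auroc_a": c.auroc_a, "auroc_b": c.auroc_b, "z": c.z,
                    "p_value": c.p_value, "method": c.method}
                for k, c in self.comparisons.items()
            },
            "metadata": self.metadata,
        }


def _series_frame(series) -> pd.DataFrame:
    if isinstance(series, RiskSeries):
        return pd.DataFrame(
            {"reference_time": series.reference_times, "score": series.scores}
        )
    times, scores = series
    return pd.DataFrame({"reference_time": pd.DatetimeIndex(times), "score": scores})


def collect_scored_observations(
    cohort: Cohort,
    score_fn,
    spec: EventWindowSpec | None = None,
    control_aggregation: str = "serial",
    case_aggregation: str = "serial",
) -> pd.DataFrame:
    """Apply ``score_fn`` (stay → hourly score series) across a cohort.

    Deteriorated stays contribute their hours inside the pre-event labeling
    interval, labeled positive; non-deteriorated stays contribute all serial
    hours, labeled negative.  ``per_patient_max`` collapses a stay's
    contribution to its single highest score, the conventional rule for
    aggregate track-and-trigger scores.
    """
    spec = spec or EventWindowSpec()
    for mode in (control_aggregation, case_aggregation):
        if mode not in ("serial", "per_patient_max"):
            raise ValueError(f"unknown aggregation mode {mode!r}")
    rows = []
    for stay in cohort:
        frame = _series_frame(score_fn(stay))
        if frame.empty:
            continue
        if stay.outcome.deteriorated:
            ev = stay.outcome.event_time
            mask = (frame["reference_time"] >= ev - spec.far_bound) & (
                frame["reference_time"] <= ev - spec.near_bound
            )
            frame, label, mode = frame[mask], 1, case_aggregation
        else:
            label, mode = 0, control_aggregation
        if frame.empty:
            continue
        if mode == "per_patient_max":
            frame = frame.loc[[frame["score"].idxmax()]]
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": stay.patient_id,
                    "reference_time": frame["reference_time"].to_numpy(),
                    "score": frame["score"].to_numpy(dtype=float),
                    "label": label,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=OBS_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def _obs_arrays(observations) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    if isinstance(observations, pd.DataFrame):
        return (
            observations["label"].to_numpy(dtype=int),
            observations["score"].to_numpy(dtype=float),
            observations["patient_id"].to_numpy(),
        )
    y, s = observations
    return np.asarray(y, dtype=int), np.asarray(s, dtype=float), None


def roc_auc(
    observations, n_boot: int = 1000, seed: int = 0
) -> AUROCResult:
    """AUROC (Mann–Whitney with ties as 1/2) and a bootstrap 95% CI.

    The CI resamples patients, not rows — case patients and control patients
    are resampled separately so every replicate keeps both classes.  With
    plain ``(y, scores)`` input each row is its own resampling unit.
    """
    y, scores, pids = _obs_arrays(observations)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC needs both classes present")
    point = float(roc_auc_score(y, scores))
    if pids is None:
        pids = np.arange(len(y)).astype(str)
    rng = np.random.default_rng(seed)
    pos_ids = np.unique(pids[y == 1])
    neg_ids = np.unique(pids[y == 0])
    by_id_pos = {p: scores[(pids == p) & (y == 1)] for p in pos_ids}
    by_id_neg = {p: scores[(pids == p) & (y == 0)] for p in neg_ids}
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ps = np.concatenate(
            [by_id_pos[p] for p in rng.choice(pos_ids, size=len(pos_ids))]
        )
        ns = np.concatenate(
            [by_id_neg[p] for p in rng.choice(neg_ids, size=len(neg_ids))]
        )
        yy = np.concatenate([np.ones(len(ps), dtype=int), np.zeros(len(ns), dtype=int)])
        boots[b] = roc_auc_score(yy, np.concatenate([ps, ns]))
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return AUROCResult(
        auroc=point,
        ci_lower=float(min(lo, point)),
        ci_upper=float(max(hi, point)),
        n_positive=int((y == 1).sum()),
        n_negative=int((y == 0).sum()),
    )


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Placement values: V10[i] = P(pos_i beats a random neg), and V01."""
    order = np.argsort(neg, kind="mergesort")
    sneg = neg[order]
    lo = np.searchsorted(sneg, pos, side="left")
    hi = np.searchsorted(sneg, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / len(neg)
    order = np.argsort(pos, kind="mergesort")
    spos = pos[order]
    lo = np.searchsorted(spos, neg, side="right")
    hi = np.searchsorted(spos, neg, side="left")
    v01 = ((len(pos) - lo) + 0.5 * (lo - hi)) / len(pos)
    return v10, v01


def compare_auroc(obs_a, obs_b) -> ComparisonResult:
    """Two-sided paired test of AUROC(a) = AUROC(b) on identical observations.

    The variance of the AUROC difference accounts for the within-patient
    correlation of the two scores through the empirical covariance of their
    placement values — the paired correlated-AUROC design.
    """
    ya, sa, ka = _obs_arrays(obs_a)
    yb, sb, kb = _obs_arrays(obs_b)
    if len(ya) != len(yb) or not np.array_equal(ya, yb):
        raise ValueError("compare_auroc requires the same observations under both scores")
    if ka is not None and kb is not None and not np.array_equal(ka, kb):
        raise ValueError("compare_auroc requires identically ordered observation sets")
    pos_a, neg_a = sa[ya == 1], sa[ya == 0]
    pos_b, neg_b = sb[yb == 1], sb[yb == 0]
    m, n = len(pos_a), len(neg_a)
    if m < 2 or n < 2:
        raise ValueError("need at least two observations per class")
    v10a, v01a = _placements(pos_a, neg_a)
    v10b, v01b = _placements(pos_b, neg_b)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0 or auc_a == auc_b:
        z = 0.0
        p = 1.0 if auc_a == auc_b else 0.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(auroc_a=auc_a, auroc_b=auc_b, z=float(z), p_value=p)


def confusion_at_threshold(
    observations,
    threshold: float,
    score_name: str = "score",
    total_patient_days: float | None = None,
) -> OperatingPoint:
    """Confusion metrics with the inclusive alarm rule score >= threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    y, scores, _ = _obs_arrays(observations)
    alarm = scores >= threshold
    tp = int((alarm & (y == 1)).sum())
    fp = int((alarm & (y == 0)).sum())
    fn = int((~alarm & (y == 1)).sum())
    tn = int((~alarm & (y == 0)).sum())

    def pct(num, den):
        return 100.0 * num / den if den else float("nan")

    fad = None
    if total_patient_days is not None:
        if total_patient_days <= 0:
            raise ValueError("total_patient_days must be positive")
        fad = fp / total_patient_days
    return OperatingPoint(
        score_name=score_name,
        threshold=float(threshold),
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        ppv=pct(tp, tp + fp),
        npv=pct(tn, tn + fn),
        false_alarms_per_day=fad,
    )


def threshold_for_sensitivity(observations, target_sensitivity: float) -> float:
    """Largest threshold achieving at least the target sensitivity (percent).

    This is the matched-sensitivity design: pick each score's threshold so
    all scores operate at the sensitivity of a reference operating point,
    then compare their specificity, predictive values and alarm burden.
    """
    if not 0.0 < target_sensitivity < 100.0:
        raise ValueError("target sensitivity must be in (0, 100)")
    y, scores, _ = _obs_arrays(observations)
    pos = np.sort(scores[y == 1])[::-1]
    if len(pos) == 0:
        raise ValueError("no positive observations")
    k = int(np.ceil(target_sensitivity / 100.0 * len(pos)))
    if k > len(pos):
        raise ValueError(f"sensitivity {target_sensitivity}% unattainable")
    return float(pos[k - 1])


def false_alarms_per_day(
    observations, threshold: float, total_patient_days: float | None = None
) -> float:
    """Control alarms at/above threshold per day of control observation.

    The default denominator is the control observation-time in the
    evaluation set itself: serial control rows are hourly, so days =
    control rows / 24.
    """
    y, scores, _ = _obs_arrays(observations)
    n_controls = int((y == 0).sum())
    if total_patient_days is None:
        total_patient_days = n_controls / 24.0
    if total_patient_days <= 0:
        raise ValueError("total_patient_days must be positive")
    fp = int(((y == 0) & (scores >= threshold)).sum())
    return fp / total_patient_days


def matched_sensitivity_table(
    observations_by_score: dict[str, pd.DataFrame],
    reference_score: str,
    reference_thresholds=(3, 4, 5),
) -> pd.DataFrame:
    """Tables-1/2-style comparison at the reference score's sensitivities.

    For each reference threshold (e.g. MEWS >= 3/4/5) every other score gets
    the largest threshold matching that sensitivity; rows report sensitivity,
    specificity, PPV, NPV and false alarms per day.
    """
    ref = observations_by_score[reference_score]
    rows = []
    for ref_thr in reference_thresholds:
        ref_days = _serial_control_days(ref)
        op = confusion_at_threshold(
            ref, ref_thr, score_name=f"{reference_score} >= {ref_thr}",
            total_patient_days=ref_days,
        )
        rows.append(vars(op))
        for name, obs in observations_by_score.items():
            if name == reference_score:
                continue
            target = float(np.clip(op.sensitivity, 1e-9, 100.0 - 1e-9))
            thr = threshold_for_sensitivity(obs, target)
            op2 = confusion_at_threshold(
                obs, thr, score_name=f"{name} >= {thr:.3g}",
                total_patient_days=_serial_control_days(obs),
            )
            rows.append(vars(op2))
    return pd.DataFrame(rows)


def _serial_control_days(obs: pd.DataFrame) -> float:
    return max(int((obs["label"] == 0).sum()), 1) / 24.0


# ---------------------------------------------------------------------------
# cross-validation of the recurrent models with a MEWS column


@dataclass
class CVResult:
    """Pooled validation observations from stay-level k-fold CV.

    ``observations`` has one row per validation window with columns
    patient_id, reference_time, label, fold and one ``score_*`` column per
    evaluated score; all scores share the identical observation set.
    """

    observations: pd.DataFrame
    k: int
    seed: int
    lookback: int
    variants: tuple[str, ...]
    models: dict = field(default_factory=dict)  # (variant, fold) -> CanEWSModel
    fold_members: dict = field(default_factory=dict)  # fold -> validation ids

    def score_frame(self, name: str) -> pd.DataFrame:
        df = self.observations
        return df[["patient_id", "reference_time", "label"]].assign(
            score=df[f"score_{name}"]
        )

    def aurocs(self, n_boot: int = 200, seed: int = 0) -> dict[str, AUROCResult]:
        names = [c.removeprefix("score_") for c in self.observations.columns
                 if c.startswith("score_")]
        return {
            name: roc_auc(self.score_frame(name), n_boot=n_boot, seed=seed)
            for name in names
        }

    def report(self, n_boot: int = 200, seed: int = 0) -> EvalReport:
        aurocs = self.aurocs(n_boot=n_boot, seed=seed)
        names = list(aurocs)
        comparisons = {}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                comparisons[f"{a} vs {b}"] = compare_auroc(
                    self.score_frame(a), self.score_frame(b)
                )
        return EvalReport(
            auroc=aurocs,
            comparisons=comparisons,
            metadata={
                "k": self.k,
                "seed": self.seed,
                "lookback": self.lookback,
                "control_aggregation": "serial",
                "n_observations": len(self.observations),
            },
        )


def _prepare_stay(stay, lookback, spec, ranges, table):
    grid = compute_deltas(resample_hourly(stay, ranges))
    windows = build_feature_windows(grid, stay.outcome, lookback, "V2", spec)
    if not windows:
        return None
    X2, y, index = stack_windows(windows)
    X1 = X2[:, :, :5]  # the level channels precede the delta channels
    item = {"X1": X1, "X2": X2, "y": y, "index": index}
    if table is not None:
        mews = pd.Series(mews_series(grid, table), index=grid.times)
        item["mews"] = mews.loc[pd.DatetimeIndex(index["reference_time"])].to_numpy()
    return item


def cross_validate(
    cohort: Cohort,
    variants: tuple[str, ...] = ("V1", "V2"),
    k: int = 10,
    seed: int = 0,
    lookback: int = 24,
    spec: EventWindowSpec | None = None,
    ranges: CleaningRanges | None = None,
    include_mews: bool = True,
    mews_table: ScoringTable | None = None,
    **config_overrides,
) -> CVResult:
    """Stay-level stratified k-fold CV; every score on the same windows.

    Per fold, one model per variant is trained on the training stays'
    windows and scores the validation stays' windows; MEWS is computed on
    the identical grid hours.  No stay's windows appear on both sides of
    any fold.  Deterministic for a given seed.
    """
    spec = spec or EventWindowSpec()
    table = mews_table or (load_scoring_table() if include_mews else None)
    prepared = {}
    for stay in cohort:
        item = _prepare_stay(stay, lookback, spec, ranges, table)
        if item is not None:
            prepared[stay.patient_id] = item

    folds = split_stratified_kfold(cohort, k=k, seed=seed)
    pooled = []
    models: dict = {}
    fold_members: dict = {}
    for fold_no, (train_cohort, val_cohort) in enumerate(folds):
        train_ids = [p for p in train_cohort.patient_ids if p in prepared]
        val_ids = [p for p in val_cohort.patient_ids if p in prepared]
        if not train_ids or not val_ids:
            continue
        y_train = np.concatenate([prepared[p]["y"] for p in train_ids])
        out = pd.concat(
            [prepared[p]["index"] for p in val_ids], ignore_index=True
        )
        out["label"] = np.concatenate([prepared[p]["y"] for p in val_ids])
        out["fold"] = fold_no
        for variant in variants:
            key = "X1" if variant == "V1" else "X2"
            X_train = np.concatenate([prepared[p][key] for p in train_ids])
            X_val = np.concatenate([prepared[p][key] for p in val_ids])
            cfg = ModelConfig(
                variant=variant,
                lookback=lookback,
                seed=seed * 1000 + fold_no,
                **config_overrides,
            )
            model = train(build_model(cfg), (X_train, y_train))
            out[f"score_{variant}"] = predict_risk(model, X_val)
            models[(variant, fold_no)] = model
        fold_members[fold_no] = list(val_ids)
        if include_mews:
            out["score_MEWS"] = np.concatenate(
                [prepared[p]["mews"] for p in val_ids]
            ).astype(float)
        pooled.append(out)
    observations = pd.concat(pooled, ignore_index=True)
    return CVResult(
        observations=observations, k=k, seed=seed, lookback=lookback,
        variants=tuple(variants), models=models, fold_members=fold_members,
    )


def lookback_sweep(
    cohort: Cohort,
    variants: tuple[str, ...] = ("V2",),
    lookbacks=(4, 8, 16, 24),
    sensitivities=(50.0, 75.0, 90.0),
    k: int = 2,
    seed: int = 0,
    **cv_kwargs,
) -> pd.DataFrame:
    """Specificity and PPV at fixed sensitivity levels per lookback period.

    Re-runs cross-validation once per lookback; rows are
    (variant, lookback, sensitivity) with the matched threshold.
    """
    rows = []
    for lb in lookbacks:
        if lb < 1:
            raise ValueError("lookback must be >= 1")
        cv = cross_validate(
            cohort, variants=variants, k=k, seed=seed, lookback=lb,
            include_mews=False, **cv_kwargs,
        )
        for variant in variants:
            obs = cv.score_frame(variant)
            for target in sensitivities:
                thr = threshold_for_sensitivity(obs, target)
                op = confusion_at_threshold(obs, thr, score_name=variant)
                rows.append(
                    {
                        "variant": variant,
                        "lookback": lb,
                        "target_sensitivity": target,
                        "threshold": thr,
                        "sensitivity": op.sensitivity,
                        "specificity": op.specificity,
                        "ppv": op.ppv,
                    }
                )
    return pd.DataFrame(rows)


def risk_trajectory(
    model: CanEWSModel,
    case_stays: list[PatientStay],
    spec: EventWindowSpec | None = None,
    ranges: CleaningRanges | None = None,
    max_offset_hours: int = 24,
) -> pd.DataFrame:
    """Mean risk score per whole hour before the event across case stays.

    For each offset h in {max_offset_hours, …, 1} the score whose reference
    time is nearest to event − h (within half an hour) enters the mean.
    Rows: offset_hours (positive = hours before event), mean_score, n.
    """
    from .model import score_stay

    cases = [s for s in case_stays if s.outcome.deteriorated]
    if not cases:
        raise ValueError("no deteriorated stays supplied")
    tol = pd.Timedelta(minutes=30)
    buckets: dict[int, list[float]] = {h: [] for h in range(1, max_offset_hours + 1)}
    for stay in cases:
        series = score_stay(model, stay, ranges=ranges, spec=spec)
        if len(series.scores) == 0:
            continue
        times = series.reference_times
        for h in buckets:
            target = stay.outcome.event_time - pd.Timedelta(hours=h)
            dist = np.abs((times - target).to_numpy())
            j = int(np.argmin(dist))
            if dist[j] <= tol.to_timedelta64():
                buckets[h].append(float(series.scores[j]))
    rows = [
        {"offset_hours": h, "mean_score": float(np.mean(v)) if v else float("nan"),
         "n": len(v)}
        for h, v in sorted(buckets.items(), reverse=True)
    ]
    if all(r["n"] == 0 for r in rows):
        raise ValueError("no case stay had scoreable pre-event coverage")
    return pd.DataFrame(rows)
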