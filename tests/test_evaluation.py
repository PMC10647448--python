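import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canews.cohort import Cohort
from canews.evaluation import (
    collect_scored_observations,
    compare_auroc,
    confusion_at_threshold,
    cross_validate,
    false_alarms_per_day,
    matched_sensitivity_table,
    risk_trajectory,
    roc_auc,
    threshold_for_sensitivity,
)
from canews.model import ModelConfig, build_model, score_stay, train
from canews.preprocessing import EventWindowSpec

from conftest import T0, make_stay


def pairwise_auroc(y, scores):
    """O(n^2) Mann-Whitney oracle with ties counted 1/2."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUROC:
    def test_perfect_separation(self):
        y = np.array([1, 1, 0, 0])
        res = roc_auc((y, np.array([9.0, 8.0, 1.0, 2.0])), n_boot=20)
        assert res.auroc == 1.0

    def test_tie_rule_hand_case(self):
        y = np.array([1, 0, 0])
        res = roc_auc((y, np.array([3.0, 1.0, 5.0])), n_boot=20)
        assert res.auroc == 0.5  # one win, one loss

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        y = np.zeros(n, dtype=int)
        y[: max(1, n // 4)] = 1
        rng.shuffle(y)
        scores = rng.integers(0, 12, size=n).astype(float)  # many ties
        res = roc_auc((y, scores), n_boot=5)
        assert abs(res.auroc - pairwise_auroc(y, scores)) < 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc((np.ones(5, dtype=int), np.arange(5.0)), n_boot=5)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.ones(40, int), np.zeros(160, int)]
        scores = rng.standard_normal(200) + y
        res = roc_auc((y, scores), n_boot=200, seed=0)
        assert res.ci_lower <= res.auroc <= res.ci_upper
        assert res.ci_upper - res.ci_lower < 0.35


class TestCompareAUROC:
    def test_score_compared_with_itself(self):
        y = np.r_[np.ones(20, int), np.zeros(80, int)]
        s = np.random.default_rng(0).standard_normal(100)
        res = compare_auroc((y, s), (y, s))
        assert res.z == 0.0 and res.p_value == 1.0

    def test_strong_alternative_detected(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(60, int), np.zeros(240, int)]
        good = y + 0.1 * rng.standard_normal(300)
        noise = rng.standard_normal(300)
        res = compare_auroc((y, good), (y, noise))
        assert res.p_value < 1e-3 and res.auroc_a > res.auroc_b

    def test_unpaired_inputs_rejected(self):
        y1 = np.array([1, 0, 0, 1])
        y2 = np.array([1, 0, 1, 0])
        s = np.arange(4.0)
        with pytest.raises(ValueError, match="same observations"):
            compare_auroc((y1, s), (y2, s))


class TestConfusion:
    # 10 hand-built observations: 4 positive, 6 negative
    Y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    S = np.array([9.0, 7.0, 4.0, 2.0, 8.0, 5.0, 3.0, 1.0, 1.0, 0.0])

    def test_hand_computed_table(self):
        # threshold 5: TP=2 (9,7), FN=2, FP=2 (8,5), TN=4
        op = confusion_at_threshold((self.Y, self.S), 5.0)
        assert op.sensitivity == 50.0
        assert op.specificity == pytest.approx(100 * 4 / 6)
        assert op.ppv == 50.0
        assert op.npv == pytest.approx(100 * 4 / 6)

    def test_threshold_below_everything(self):
        op = confusion_at_threshold((self.Y, self.S), -1.0)
        assert op.sensitivity == 100.0 and op.specificity == 0.0

    def test_threshold_above_everything(self):
        op = confusion_at_threshold((self.Y, self.S), 99.0)
        assert op.sensitivity == 0.0
        assert op.npv == pytest.approx(100 * 6 / 10)  # prevalence complement

    def test_bayes_identities(self):
        """PPV/NPV follow from sensitivity, specificity and prevalence."""
        for thr in (2.0, 4.0, 5.0, 8.0):
            op = confusion_at_threshold((self.Y, self.S), thr)
            se, sp = op.sensitivity / 100, op.specificity / 100
            p = self.Y.mean()
            expected_ppv = 100 * se * p / (se * p + (1 - sp) * (1 - p))
            assert op.ppv == pytest.approx(expected_ppv)


class TestMatchedSensitivity:
    Y = np.array([1] * 10 + [0] * 30)
    S = np.concatenate([np.linspace(1, 10, 10), np.linspace(0.5, 6.0, 30)])

    def test_fixed_point(self):
        op = confusion_at_threshold((self.Y, self.S), 5.0)
        thr = threshold_for_sensitivity((self.Y, self.S), op.sensitivity)
        back = confusion_at_threshold((self.Y, self.S), thr)
        assert back.sensitivity == op.sensitivity

    def test_monotone_in_target(self):
        thresholds = [
            threshold_for_sensitivity((self.Y, self.S), t) for t in (30, 50, 70, 90)
        ]
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))

    def test_hand_quantile(self):
        # 60% of 10 positives -> 6th largest positive score = 5
        assert threshold_for_sensitivity((self.Y, self.S), 60.0) == 5.0

    def test_unattainable_rejected(self):
        with pytest.raises(ValueError):
            threshold_for_sensitivity((self.Y, self.S), 100.0)


class TestFalseAlarms:
    def test_hand_rate(self):
        y = np.r_[np.ones(2, int), np.zeros(288, int)]
        scores = np.r_[np.full(2, 9.0), np.full(6, 5.0), np.full(282, 0.0)]
        # 6 control alarms over 288 control-hours = 12 control-days
        assert false_alarms_per_day((y, scores), 4.0) == pytest.approx(0.5)

    def test_none_above_threshold(self):
        y = np.r_[np.ones(2, int), np.zeros(48, int)]
        scores = np.r_[np.full(2, 9.0), np.zeros(48)]
        assert false_alarms_per_day((y, scores), 1.0) == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(5, int), np.zeros(95, int)]
        scores = rng.random(100) * 10
        rates = [false_alarms_per_day((y, scores), t) for t in np.linspace(0, 10, 21)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestCollect:
    def _score_fn(self, stay):
        """Deterministic toy score: hour index within the stay."""
        times = pd.date_range(
            stay.admission_time.ceil("h"), stay.discharge_time, freq="1h"
        )
        return times, np.arange(len(times), dtype=float)

    def test_control_per_patient_max(self):
        stay = make_stay(n_hours=30)
        obs = collect_scored_observations(
            Cohort([stay]), self._score_fn, control_aggregation="per_patient_max"
        )
        assert len(obs) == 1
        assert obs["score"].iloc[0] == obs["score"].max() == 29.0
        assert obs["label"].iloc[0] == 0

    def test_case_event_window_rows(self):
        event = T0 + pd.Timedelta(hours=30)
        stay = make_stay(n_hours=31, deteriorated=True, event_time=event,
                         discharge=event)
        obs = collect_scored_observations(Cohort([stay]), self._score_fn)
        assert (obs["label"] == 1).all()
        assert len(obs) <= 24
        assert obs["reference_time"].max() <= event - pd.Timedelta(minutes=30)
        assert obs["reference_time"].min() >= event - pd.Timedelta(hours=24)

    def test_empty_cohort(self):
        obs = collect_scored_observations(Cohort([]), self._score_fn)
        assert obs.empty


@pytest.fixture(scope="module")
def toy_cohort():
    stays = []
    rng = np.random.default_rng(7)
    for i in range(16):
        deteriorated = i < 4
        start = pd.Timestamp("2018-01-01") + pd.Timedelta(days=i)
        n_hours = 60
        event = start + pd.Timedelta(hours=n_hours - 1) if deteriorated else None
        hr = rng.normal(80, 5, n_hours)
        if deteriorated:
            hr = hr + np.linspace(0, 50, n_hours)  # rising tachycardia
        stays.append(
            make_stay(
                f"P{i}", n_hours=n_hours, start=start, hr=hr,
                deteriorated=deteriorated, event_time=event,
                discharge=event if deteriorated else None,
            )
        )
    return Cohort(stays)


@pytest.fixture(scope="module")
def cv(toy_cohort):
    return cross_validate(
        toy_cohort, variants=("V2",), k=2, seed=0, lookback=12,
        max_epochs=3, batch_size=128, patience=3,
    )


class TestCrossValidateAndTrajectory:
    def test_fold_reports_and_pooled_counts(self, cv, toy_cohort):
        assert set(cv.observations["fold"]) == {0, 1}
        # pooled rows = all eligible validation windows across folds
        assert len(cv.observations) > 0
        assert set(cv.observations["patient_id"]) == set(toy_cohort.patient_ids)

    def test_no_leakage_across_folds(self, cv):
        """Each stay's windows appear in exactly one validation fold."""
        by_patient = cv.observations.groupby("patient_id")["fold"].nunique()
        assert (by_patient == 1).all()

    def test_scores_share_observation_set(self, cv):
        assert {"score_V2", "score_MEWS"} <= set(cv.observations.columns)
        assert cv.observations[["score_V2", "score_MEWS"]].notna().all().all()

    def test_report_structure(self, cv):
        report = cv.report(n_boot=20)
        assert set(report.auroc) == {"V2", "MEWS"}
        assert "V2 vs MEWS" in report.comparisons
        for res in report.auroc.values():
            assert res.ci_lower <= res.auroc <= res.ci_upper

    def test_matched_sensitivity_table_shape(self, cv):
        table = matched_sensitivity_table(
            {"MEWS": cv.score_frame("MEWS"), "V2": cv.score_frame("V2")},
            reference_score="MEWS", reference_thresholds=(1, 2),
        )
        assert len(table) == 4  # (MEWS + V2) x 2 reference thresholds

    def test_trajectory_single_case_is_own_scores(self, toy_cohort, cv):
        model = cv.models[("V2", 0)]
        case = next(s for s in toy_cohort if s.outcome.deteriorated)
        traj = risk_trajectory(model, [case], max_offset_hours=12)
        series = score_stay(model, case)
        lookup = dict(zip(series.reference_times, series.scores))
        for row in traj.itertuples():
            if row.n:
                target = case.outcome.event_time - pd.Timedelta(hours=row.offset_hours)
                assert row.mean_score == pytest.approx(lookup[target.floor("h")], abs=1e-9)

    def test_trajectory_requires_cases(self, cv, toy_cohort):
        control = next(s for s in toy_cohort if not s.outcome.deteriorated)
        with pytest.raises(ValueError):
            risk_trajectory(cv.models[("V2", 0)], [control])
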