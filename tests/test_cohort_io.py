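import numpy as np
import pandas as pd
import pytest

from canews.cohort import (
    AVPU,
    Cohort,
    CohortValidationError,
    PatientStay,
    SchemaError,
    StayOutcome,
    apply_exclusions,
    read_cohort,
    split_stratified_kfold,
    split_temporal,
    write_cohort,
)
from canews.synth import SimConfig, simulate_cohort

from conftest import make_stay


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path, small_cohort):
        """Write then read reproduces observations and outcomes field-for-field."""
        obs_p, out_p = tmp_path / "obs.csv", tmp_path / "out.csv"
        write_cohort(small_cohort, obs_p, out_p)
        back = read_cohort(obs_p, out_p)
        assert len(back) == len(small_cohort)
        for a, b in zip(small_cohort, back):
            assert a.patient_id == b.patient_id
            assert a.admission_time == b.admission_time
            assert a.discharge_time == b.discharge_time
            assert a.outcome == b.outcome
            pd.testing.assert_frame_equal(a.observations, b.observations)

    def test_round_trip_on_simulated_cohorts(self, tmp_path):
        """Round-trip holds on randomized cohorts, missing cells included."""
        for seed in (0, 1, 2):
            cohort, _ = simulate_cohort(
                SimConfig(n_stays=8, seed=seed, event_prevalence=0.3,
                          stay_hours_median=60.0, missing_rate=0.15)
            )
            obs_p, out_p = tmp_path / f"o{seed}.csv", tmp_path / f"u{seed}.csv"
            write_cohort(cohort, obs_p, out_p)
            back = read_cohort(obs_p, out_p)
            for a, b in zip(cohort, back):
                assert a.outcome == b.outcome
                pd.testing.assert_frame_equal(
                    a.observations, b.observations, check_exact=False
                )

    def test_all_missing_column_preserved(self, tmp_path):
        stay = make_stay(bt=np.nan)
        obs_p, out_p = tmp_path / "obs.csv", tmp_path / "out.csv"
        write_cohort(Cohort([stay]), obs_p, out_p)
        back = read_cohort(obs_p, out_p)
        assert back.stays[0].observations["bt"].isna().all()

    def test_observation_row_count(self, tmp_path):
        cohort, _ = simulate_cohort(SimConfig(n_stays=20, seed=3))
        obs_p, out_p = tmp_path / "obs.csv", tmp_path / "out.csv"
        write_cohort(cohort, obs_p, out_p)
        n_rows = len(pd.read_csv(obs_p))
        assert n_rows == sum(len(s.observations) for s in cohort)

    def test_non_numeric_vital_becomes_missing(self, tmp_path):
        (tmp_path / "obs.csv").write_text(
            "patient_id,timestamp,sbp,hr,rr,bt,consciousness\n"
            "P1,2020-01-01T10:00:00,err,80,12,36.6,A\n"
            "P1,2020-01-01T12:00:00,118,82,13,36.5,A\n"
        )
        (tmp_path / "out.csv").write_text(
            "patient_id,admission_time,discharge_time,deteriorated,event_time,event_type\n"
            "P1,2020-01-01T09:00:00,2020-01-02T09:00:00,0,,\n"
        )
        cohort = read_cohort(tmp_path / "obs.csv", tmp_path / "out.csv")
        obs = cohort.stays[0].observations
        assert np.isnan(obs["sbp"].iloc[0]) and obs["sbp"].iloc[1] == 118

    def test_missing_column_names_the_column(self, tmp_path):
        (tmp_path / "obs.csv").write_text(
            "patient_id,timestamp,sbp,hr,rr,consciousness\nP1,2020-01-01T10:00:00,120,80,12,A\n"
        )
        (tmp_path / "out.csv").write_text(
            "patient_id,admission_time,discharge_time,deteriorated,event_time,event_type\n"
            "P1,2020-01-01T09:00:00,2020-01-02T09:00:00,0,,\n"
        )
        with pytest.raises(SchemaError, match="bt"):
            read_cohort(tmp_path / "obs.csv", tmp_path / "out.csv")

    def test_deteriorated_without_event_time_rejected(self, tmp_path):
        (tmp_path / "obs.csv").write_text(
            "patient_id,timestamp,sbp,hr,rr,bt,consciousness\n"
            "P7,2020-01-01T10:00:00,120,80,12,36.6,A\n"
        )
        (tmp_path / "out.csv").write_text(
            "patient_id,admission_time,discharge_time,deteriorated,event_time,event_type\n"
            "P7,2020-01-01T09:00:00,2020-01-02T09:00:00,1,,ICU\n"
        )
        with pytest.raises(CohortValidationError, match="P7"):
            read_cohort(tmp_path / "obs.csv", tmp_path / "out.csv")

    def test_event_before_admission_rejected(self, tmp_path):
        (tmp_path / "obs.csv").write_text(
            "patient_id,timestamp,sbp,hr,rr,bt,consciousness\n"
            "P1,2020-01-05T10:00:00,120,80,12,36.6,A\n"
        )
        (tmp_path / "out.csv").write_text(
            "patient_id,admission_time,discharge_time,deteriorated,event_time,event_type\n"
            "P1,2020-01-05T09:00:00,2020-01-06T09:00:00,1,2020-01-01T00:00:00,ICU\n"
        )
        with pytest.raises(CohortValidationError):
            read_cohort(tmp_path / "obs.csv", tmp_path / "out.csv")

    def test_duplicate_timestamps_keep_last(self, tmp_path):
        (tmp_path / "obs.csv").write_text(
            "patient_id,timestamp,sbp,hr,rr,bt,consciousness\n"
            "P1,2020-01-01T10:00:00,120,80,12,36.6,A\n"
            "P1,2020-01-01T10:00:00,95,80,12,36.6,A\n"
        )
        (tmp_path / "out.csv").write_text(
            "patient_id,admission_time,discharge_time,deteriorated,event_time,event_type\n"
            "P1,2020-01-01T09:00:00,2020-01-02T09:00:00,0,,\n"
        )
        with pytest.warns(UserWarning, match="duplicate"):
            cohort = read_cohort(tmp_path / "obs.csv", tmp_path / "out.csv")
        assert cohort.stays[0].observations["sbp"].tolist() == [95.0]


class TestExclusions:
    def test_case_without_recent_vitals_excluded(self):
        # last observation 30 h before the event
        event = pd.Timestamp("2018-03-05 00:00")
        stay = make_stay(
            "X", n_hours=10, start=event - pd.Timedelta(hours=39),
            deteriorated=True, event_time=event, discharge=event,
        )
        kept, log = apply_exclusions(Cohort([stay]))
        assert len(kept) == 0 and log["no_vitals_24h_pre_event"] == 1

    def test_short_span_excluded(self):
        stay = make_stay("Y", n_hours=3, step=pd.Timedelta(minutes=5))
        kept, log = apply_exclusions(Cohort([stay]))
        assert len(kept) == 0 and log["span_under_30min"] == 1

    def test_healthy_long_stay_retained(self):
        stay = make_stay("Z", n_hours=120)
        kept, _ = apply_exclusions(Cohort([stay]))
        assert kept.patient_ids == ["Z"]


class TestSplits:
    def test_temporal_boundary_and_partition(self, small_cohort):
        cutoff = pd.Timestamp("2018-06-02 12:30")  # exactly B's admission
        train, test = split_temporal(small_cohort, cutoff)
        assert train.patient_ids == ["A"]
        assert test.patient_ids == ["B", "C"]  # admission at cutoff -> test
        assert len(train) + len(test) == len(small_cohort)

    def test_temporal_cutoff_before_everything(self, small_cohort):
        train, test = split_temporal(small_cohort, pd.Timestamp("2000-01-01"))
        assert len(train) == 0 and len(test) == 3

    def _cohort(self, n, n_events):
        stays = []
        for i in range(n):
            stays.append(
                make_stay(
                    f"P{i}", n_hours=30,
                    start=pd.Timestamp("2018-01-01") + pd.Timedelta(days=i),
                    deteriorated=i < n_events,
                    event_time=pd.Timestamp("2018-01-01")
                    + pd.Timedelta(days=i, hours=29),
                )
            )
        return Cohort(stays)

    def test_balanced_folds(self):
        folds = split_stratified_kfold(self._cohort(20, 10), k=2, seed=0)
        for _, val in folds:
            assert val.n_events == 5

    def test_fold_determinism_and_partition(self):
        cohort = self._cohort(100, 10)
        a = split_stratified_kfold(cohort, k=10, seed=7)
        b = split_stratified_kfold(cohort, k=10, seed=7)
        val_ids_a = [tuple(v.patient_ids) for _, v in a]
        assert val_ids_a == [tuple(v.patient_ids) for _, v in b]
        # validation folds partition the cohort
        flat = [p for ids in val_ids_a for p in ids]
        assert sorted(flat) == sorted(cohort.patient_ids)

    def test_pigeonhole_event_counts(self):
        folds = split_stratified_kfold(self._cohort(100, 19), k=10, seed=1)
        assert {v.n_events for _, v in folds} <= {1, 2}

    def test_too_few_events_errors(self):
        with pytest.raises(ValueError, match="deteriorated"):
            split_stratified_kfold(self._cohort(20, 3), k=5, seed=0)


def test_avpu_order():
    assert list(AVPU) == sorted(AVPU) and [int(l) for l in AVPU] == [0, 1, 2, 3]


def test_optional_dbp_column_round_trips_but_is_never_modelled(tmp_path):
    """A dbp column is accepted, cleaned-compatible, and preserved on write."""
    (tmp_path / "obs.csv").write_text(
        "patient_id,timestamp,sbp,hr,rr,bt,consciousness,dbp\n"
        "P1,2020-01-01T10:00:00,120,80,12,36.6,A,70\n"
        "P1,2020-01-01T12:00:00,118,82,13,36.5,A,err\n"
    )
    (tmp_path / "out.csv").write_text(
        "patient_id,admission_time,discharge_time,deteriorated,event_time,event_type\n"
        "P1,2020-01-01T09:00:00,2020-01-02T09:00:00,0,,\n"
    )
    cohort = read_cohort(tmp_path / "obs.csv", tmp_path / "out.csv")
    obs = cohort.stays[0].observations
    assert obs["dbp"].iloc[0] == 70.0 and np.isnan(obs["dbp"].iloc[1])
    write_cohort(cohort, tmp_path / "obs2.csv", tmp_path / "out2.csv")
    back = read_cohort(tmp_path / "obs2.csv", tmp_path / "out2.csv")
    pd.testing.assert_frame_equal(back.stays[0].observations, obs)
    # the hourly grid (model input) carries only the five vitals
    from canews.preprocessing import resample_hourly

    grid = resample_hourly(cohort.stays[0])
    assert "dbp" not in grid.values.columns
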