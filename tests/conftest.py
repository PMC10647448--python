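import numpy as np
import pandas as pd
import pytest

from canews.cohort import Cohort, PatientStay, StayOutcome

T0 = pd.Timestamp("2018-03-01 08:00")


def make_stay(
    patient_id="S1",
    n_hours=48,
    start=T0,
    step=pd.Timedelta(hours=1),
    sbp=120.0,
    hr=80.0,
    rr=12.0,
    bt=36.6,
    consciousness=0.0,
    deteriorated=False,
    event_time=None,
    discharge=None,
):
    """A stay with regularly charted, constant (or per-hour listed) vitals."""
    times = pd.date_range(start, periods=n_hours, freq=step)

    def expand(v):
        return np.full(n_hours, v, dtype=float) if np.isscalar(v) else np.asarray(v, float)

    obs = pd.DataFrame(
        {
            "timestamp": times,
            "sbp": expand(sbp),
            "hr": expand(hr),
            "rr": expand(rr),
            "bt": expand(bt),
            "consciousness": expand(consciousness),
        }
    )
    if discharge is None:
        # end the stay at the last charted hour so an n-hour observation
        # series yields exactly n grid hours
        discharge = times[-1] if n_hours > 1 else times[-1] + pd.Timedelta(hours=1)
    outcome = StayOutcome(
        deteriorated=deteriorated,
        event_time=event_time if deteriorated else None,
        event_type="ICU" if deteriorated else None,
    )
    return PatientStay(
        patient_id=patient_id,
        admission_time=start,
        discharge_time=discharge,
        observations=obs,
        outcome=outcome,
    )


@pytest.fixture
def normal_stay():
    return make_stay()


@pytest.fixture
def small_cohort():
    """Three healthy stays with distinct admission dates."""
    stays = [
        make_stay("A", n_hours=30, start=pd.Timestamp("2017-05-01 06:00")),
        make_stay("B", n_hours=40, start=pd.Timestamp("2018-06-02 12:30"), hr=90.0),
        make_stay("C", n_hours=26, start=pd.Timestamp("2019-07-03 22:15"), rr=14.0),
    ]
    return Cohort(stays)
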