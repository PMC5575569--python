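import datetime as dt

import pytest
from hypothesis import settings, HealthCheck

import streetcount as sc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SURVEY_DATE = dt.date(2016, 3, 1)


def make_record(
    dog_class=sc.DogClass.MALE,
    bcs=3,
    skin=sc.SkinCondition.ABSENT,
    point=(18.95, 72.80),
    date=SURVEY_DATE,
    second=0,
):
    return sc.DogRecord(
        timestamp=dt.datetime.combine(date, dt.time(7, 0)) + dt.timedelta(seconds=second),
        point=point,
        dog_class=dog_class,
        bcs=bcs,
        skin_condition=skin,
    )


def make_replicate(route_id, n_records, date=SURVEY_DATE, **record_kw):
    recs = [make_record(date=date, second=i, **record_kw) for i in range(n_records)]
    return sc.ReplicateSurvey(route_id=route_id, survey_date=date, records=recs)


@pytest.fixture
def label_map():
    return sc.default_label_map()


@pytest.fixture
def small_params():
    return sc.SimParams(n_routes=3, route_length_km=5.0, lambda_per_km=4.0, seed=11)


@pytest.fixture
def sim_route(small_params):
    return sc.simulate_route(small_params, 0)
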