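"""Shared fixtures: deterministic hypothesis profile, a constant feed series
and the three-animal toy herd used by the worksheet-oracle tests."""
from __future__ import annotations

from datetime import date

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from herdlca.feed import FeedQualitySeries
from herdlca.params import ParameterSet
from herdlca.tier2 import AnimalRecord, WeighingEvent

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def const_feed() -> FeedQualitySeries:
    """Single-sample (hence constant) DE/CP per feed type for farmlet X."""
    rows = [
        ("X", "pasture", date(2015, 1, 1), 77.0, 20.0),
        ("X", "silage", date(2015, 1, 1), 65.0, 11.5),
    ]
    return FeedQualitySeries(
        pd.DataFrame(rows, columns=list(FeedQualitySeries.COLUMNS))
    )


def _animal(animal_id: str, sex: str, events) -> AnimalRecord:
    return AnimalRecord(
        animal_id, "X", sex,
        tuple(WeighingEvent(d, w, loc) for d, w, loc in events),
    )


@pytest.fixture(scope="session")
def toy_herd() -> list[AnimalRecord]:
    """Three animals covering pasture, housing and a weight-loss period."""
    d = date(2015, 5, 1)

    def plus(days):
        from datetime import timedelta
        return d + timedelta(days=days)

    t1 = _animal("T1", "steer", [
        (d, 300.0, "pasture"), (plus(21), 321.0, "housing"),
        (plus(49), 335.0, "pasture"),
    ])
    t2 = _animal("T2", "heifer", [
        (d, 280.0, "pasture"), (plus(28), 300.8, "pasture"),
        (plus(42), 308.2, "pasture"),
    ])
    t3 = _animal("T3", "steer", [
        (d, 350.0, "housing"), (plus(21), 344.0, "pasture"),
        (plus(42), 365.0, "pasture"),
    ])
    return [t1, t2, t3]
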