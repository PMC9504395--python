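import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from opinionpulse import TweetRecord, default_surname_table
from opinionpulse.synthetic import SyntheticConfig, constant_theta_schedule, date_span

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def surname_table():
    return default_surname_table()


@pytest.fixture
def tiny_corpus():
    d = dt.date(2020, 10, 5)
    return [
        TweetRecord("m1", d, "Got my first dose of Pfizer today", "CA",
                    "Washington", "positive"),
        TweetRecord("m2", d, "worried about the side effect and fever", "CA",
                    "Chen", "negative"),
        TweetRecord("m3", d + dt.timedelta(days=1), "vaccines are great",
                    "NY", None, "neutral"),
    ]


def small_config(n_days=30, base_rate=40.0, theta=(0.5, 0.3, 0.2), seed=7,
                 regions=None, **kw):
    start = dt.date(2020, 10, 1)
    end = start + dt.timedelta(days=n_days - 1)
    regions = regions or {"CA": 2_000_000, "WY": 500_000}
    return SyntheticConfig(
        start=start, end=end, regions=regions, base_rate=base_rate,
        pop_ref=1_000_000.0,
        theta_schedule=constant_theta_schedule(date_span(start, end), theta),
        seed=seed, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20201001)
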