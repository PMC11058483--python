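import datetime as dt

import numpy as np
import pandas as pd
import pytest

import thermolag as tl
from thermolag.events import covered_instances


def random_series(seed: int, n_days: int = 1000,
                  start: str = "2014-01-01") -> tl.TemperatureSeries:
    """Seasonal + noise daily series long enough to cover full warm and
    cold windows."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(float)
    temps = 13.0 + 15.0 * np.cos(2 * np.pi * (doy - 197) / 365.2425)
    temps = temps + rng.normal(0, 3.5, n_days)
    return tl.TemperatureSeries(pd.Series(temps, index=dates))


def oracle_event_days(series: tl.TemperatureSeries, definition,
                      threshold: float) -> set:
    """Independent brute-force oracle: a day is an event day iff it sits
    inside some block of exactly ``min_duration`` consecutive calendar
    days that all lie in a covered window instance, all have data, and
    all meet the threshold.  (Membership in a qualifying block is
    equivalent to membership in a maximal qualifying run.)"""
    window, d_min = definition.window, definition.min_duration
    in_window = set()
    for first, last in covered_instances(window, series.start, series.end):
        in_window.update(d.date()
                         for d in pd.date_range(first, last, freq="D"))
    temps = {ts.date(): v for ts, v in series.data.items()}

    def qualifies(day):
        if day not in in_window:
            return False
        t = temps.get(day, np.nan)
        if np.isnan(t):
            return False
        return t >= threshold if definition.kind == "heat" else t <= threshold

    out = set()
    for day in in_window:
        for j in range(d_min):
            block = [day + dt.timedelta(days=i - j) for i in range(d_min)]
            if all(qualifies(b) for b in block):
                out.add(day)
                break
    return out


@pytest.fixture(scope="session")
def demo_series():
    return random_series(seed=42, n_days=1200)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study with one injected heat effect, shared by
    read-only tests."""
    truth = tl.default_truth(responses=("hb",), exposure_effects=[
        tl.ExposureEffect("hb", "HW05", "lag1", 2.6)])
    cohort = tl.CohortParams(n_subjects=250, visit_rate=2.0,
                             start_date=dt.date(2013, 1, 8),
                             end_date=dt.date(2017, 12, 31))
    climate = tl.ClimateParams(end_date=dt.date(2017, 12, 31))
    return tl.simulate_study(climate=climate, cohort=cohort, truth=truth,
                             use_network=False, seed=20)
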