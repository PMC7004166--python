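import datetime as dt

import numpy as np
import pandas as pd
import pytest

from musthtrack.trackio import Track


def make_track(individual_id="B1", start="2012-01-01 00:00", n=72,
               step_min=60, lat0=0.5, lon0=37.5, speed_kmh=0.4, seed=0):
    """Small correlated-walk track for preprocessing tests."""
    rng = np.random.default_rng(seed)
    ts = pd.date_range(start, periods=n, freq=f"{step_min}min", tz="UTC")
    heading = rng.uniform(0, 2 * np.pi)
    step_km = speed_kmh * step_min / 60.0
    x = np.zeros(n)
    y = np.zeros(n)
    for i in range(1, n):
        heading += rng.normal(0, 0.6)
        x[i] = x[i - 1] + step_km * np.cos(heading)
        y[i] = y[i - 1] + step_km * np.sin(heading)
    lat = lat0 + y / 111.1949266
    lon = lon0 + x / 111.1949266
    fixes = pd.DataFrame({"timestamp": ts, "lat": lat, "lon": lon,
                          "interpolated": False})
    return Track(individual_id=individual_id, fixes=fixes)


@pytest.fixture
def hourly_track():
    return make_track(n=96, step_min=60)


def day_fixes(speeds_km, start="2012-01-01 21:00", lat0=0.0, lon0=37.0,
              headings=None, seed=0):
    """Fixes with given consecutive hourly step lengths (km)."""
    rng = np.random.default_rng(seed)
    n = len(speeds_km) + 1
    ts = pd.date_range(start, periods=n, freq="h", tz="UTC")
    if headings is None:
        headings = rng.uniform(0, 2 * np.pi, size=len(speeds_km))
    x = np.concatenate([[0.0], np.cumsum(np.asarray(speeds_km) * np.cos(headings))])
    y = np.concatenate([[0.0], np.cumsum(np.asarray(speeds_km) * np.sin(headings))])
    return pd.DataFrame({"timestamp": ts, "lat": lat0 + y / 111.1949266,
                         "lon": lon0 + x / 111.1949266, "interpolated": False})
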