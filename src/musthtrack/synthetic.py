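"""Synthetic elephant-like tracking data with known musth ground truth.

The generator emulates the statistical structure the analysis assumes:
each individual-day has a latent log mean-speed level built from a
non-musth baseline with an age trend, a per-individual random effect,
AR1 day-to-day noise, and a musth state shift; 24 hourly steps of a
correlated walk are then laid out so the day's realised mean step length
equals that level. Musth bouts are contiguous: one long (~60-day) bout
per year for bulls 35 and over, several short (~2-week) bouts per year
for younger bulls. Sightings are Bernoulli per day and carry the field
signal count (2-3 in musth, 0 outside, occasionally a single ambiguous
signal to exercise the exclusion rule).

Musth multiplies the expected daily speed by ``musth_multiplier`` (2.14
by default) and its day-to-day standard deviation by
``musth_sd_multiplier`` (2.11), via exact lognormal moment matching.

Everything is deterministic given the seed. Environmental fields (smooth
random elevation, 16-day seasonal NDVI composites, one river, one
protected rectangle) are generated on small grids so the whole covariate
path is testable without any satellite download.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Polygon

from .covariates import NDVI_WINDOW_DAYS, AsciiGrid, CovariateStack
from .geo import AzimuthalEquidistant
from .musth_hmm import HmmWindow
from .trackio import Track

#: Default ages mirror the detection subset: bulls from late 20s to early 50s.
DEFAULT_AGES = {"B01": 28, "B02": 30, "B03": 32, "B04": 33, "B05": 34,
                "B06": 36, "B07": 38, "B08": 42, "B09": 47, "B10": 52}

DEFAULT_EXTENT = (0.3, 0.8, 37.0, 38.0)  # lat_min, lat_max, lon_min, lon_max


@dataclass
class SimConfig:
    ages: dict = field(default_factory=lambda: dict(DEFAULT_AGES))
    start_date: dt.date = dt.date(2012, 1, 1)
    n_days: int = 300
    extent: tuple = DEFAULT_EXTENT
    nonmusth_speed_kmh: float = 0.3     # expected non-musth daily mean speed at age 35
    age_slope_log: float = -0.005       # non-musth log-speed trend per year of age
    musth_multiplier: float = 2.14      # musth / non-musth expected-speed ratio
    musth_sd_multiplier: float = 2.11   # musth / non-musth speed-SD ratio
    day_sd_log: float = 0.15            # stationary SD of daily log-level noise
    ar1_phi: float = 0.4                # day-to-day AR1 of the level noise
    indiv_sd_log: float = 0.15          # SD of per-individual random intercept
    bout_long_days: float = 60.0        # ~2 months, bulls >= 35
    bout_short_days: float = 14.0       # ~2 weeks, younger bulls
    bouts_per_year_young: int = 3
    age_threshold: float = 35.0
    turn_sd_rad: float = 0.8            # heading innovation SD of the hourly walk
    step_shape: float = 2.0             # gamma shape of raw hourly step lengths
    sighting_rate: float = 0.05         # per-day observation probability
    one_signal_fraction: float = 0.05   # sightings degraded to a single signal
    missing_rate: float = 0.0           # per-fix dropout probability
    seed: int = 0

    def __post_init__(self):
        if self.musth_multiplier <= 0 or self.musth_sd_multiplier <= 0:
            raise ValueError("multipliers must be positive")
        for r in (self.sighting_rate, self.one_signal_fraction, self.missing_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# environment

def make_environment(extent: tuple = DEFAULT_EXTENT, grid: int = 120,
                     seed: int = 0, start_date: dt.date = dt.date(2012, 1, 1),
                     n_days: int = 300) -> CovariateStack:
    """Deterministic synthetic covariate stack covering the extent.

    Smooth random elevation (so slope and VRM are non-trivial), seasonal
    sinusoidal NDVI at a 16-day cadence spanning the simulation dates, a
    meandering river polyline and a rectangular protected area.
    """
    lat_min, lat_max, lon_min, lon_max = extent
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    cell = (lon_max - lon_min) / grid
    nrows = max(int(round((lat_max - lat_min) / cell)), 8)
    elev = gaussian_filter(rng.normal(size=(nrows, grid)), sigma=6) * 400.0 + 800.0
    elevation = AsciiGrid(values=elev, xll=lon_min, yll=lat_min, cellsize=cell)

    base = gaussian_filter(rng.normal(size=(nrows, grid)), sigma=10) * 0.15 + 0.35
    ndvi = {}
    start = start_date - dt.timedelta(days=NDVI_WINDOW_DAYS)
    total = n_days + 2 * NDVI_WINDOW_DAYS
    for off in range(0, total, NDVI_WINDOW_DAYS):
        d = start + dt.timedelta(days=off)
        # biannual rains -> roughly six-month greenness cycle
        season = 0.2 * math.sin(2.0 * math.pi * d.timetuple().tm_yday / 182.5)
        vals = np.clip(base + season, -1.0, 1.0)
        ndvi[d] = AsciiGrid(values=vals, xll=lon_min, yll=lat_min, cellsize=cell)

    lats = np.linspace(lat_min, lat_max, 20)
    lons = (lon_min + (lon_max - lon_min)
            * (0.5 + 0.2 * np.sin(np.linspace(0, 3 * math.pi, 20))))
    river = LineString([(lo, la) for lo, la in zip(lons, lats)])
    dlat, dlon = lat_max - lat_min, lon_max - lon_min
    protected = Polygon([
        (lon_min + 0.25 * dlon, lat_min + 0.25 * dlat),
        (lon_min + 0.75 * dlon, lat_min + 0.25 * dlat),
        (lon_min + 0.75 * dlon, lat_min + 0.75 * dlat),
        (lon_min + 0.25 * dlon, lat_min + 0.75 * dlat),
    ])
    return CovariateStack(elevation=elevation, ndvi=ndvi, water=river,
                          protected=protected)


# ---------------------------------------------------------------------------
# musth schedules and day levels

def _bout_schedule(age: float, n_days: int, cfg: SimConfig, rng) -> np.ndarray:
    """Boolean musth mask over the simulated days; bouts are contiguous."""
    mask = np.zeros(n_days, bool)
    old = age >= cfg.age_threshold
    mean_len = cfg.bout_long_days if old else cfg.bout_short_days
    per_year = 1 if old else cfg.bouts_per_year_young
    n_years = max(n_days / 365.0, 1e-9)
    n_bouts = max(1, int(round(per_year * n_years)))
    for _ in range(n_bouts):
        length = max(3, int(round(rng.normal(mean_len, 0.15 * mean_len))))
        start = int(rng.integers(0, max(n_days - length, 1)))
        mask[start:start + length] = True
    return mask


def _lognormal_musth_shift(cfg: SimConfig) -> tuple[float, float]:
    """(log-mean shift, musth log-SD) giving exact mean x multiplier and
    SD x sd_multiplier on the natural scale."""
    s0 = cfg.day_sd_log
    cv0_sq = math.expm1(s0 ** 2)
    cv_m_sq = cv0_sq * (cfg.musth_sd_multiplier / cfg.musth_multiplier) ** 2
    s_m = math.sqrt(math.log1p(cv_m_sq))
    shift = math.log(cfg.musth_multiplier) - 0.5 * (s_m ** 2 - s0 ** 2)
    return shift, s_m


def simulate_day_levels(cfg: SimConfig) -> pd.DataFrame:
    """Latent daily mean-speed levels and true states for every
    individual-day: columns individual_id, date, age, state, speed_kmh."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 29]))
    shift, s_m = _lognormal_musth_shift(cfg)
    s0 = cfg.day_sd_log
    rows = []
    for ind, age in cfg.ages.items():
        b_i = rng.normal(0.0, cfg.indiv_sd_log)
        musth = _bout_schedule(age, cfg.n_days, cfg, rng)
        # AR1 noise with stationary SD 1
        e = np.empty(cfg.n_days)
        e[0] = rng.normal()
        innov = rng.normal(size=cfg.n_days) * math.sqrt(1.0 - cfg.ar1_phi ** 2)
        for t in range(1, cfg.n_days):
            e[t] = cfg.ar1_phi * e[t - 1] + innov[t]
        mu0 = (math.log(cfg.nonmusth_speed_kmh) - 0.5 * s0 ** 2
               + cfg.age_slope_log * (age - cfg.age_threshold) + b_i)
        for d in range(cfg.n_days):
            sd = s_m if musth[d] else s0
            lvl = mu0 + (shift if musth[d] else 0.0) + sd * e[d]
            rows.append({"individual_id": ind,
                         "date": cfg.start_date + dt.timedelta(days=d),
                         "age": age,
                         "state": "musth" if musth[d] else "non_musth",
                         "speed_kmh": math.exp(lvl)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hourly tracks

def simulate_tracks(cfg: SimConfig,
                    levels: pd.DataFrame | None = None
                    ) -> tuple[dict[str, Track], pd.DataFrame]:
    """Hourly fixes realising the daily levels, plus the ground truth.

    Tracks are simulated as correlated walks on the local projected plane
    (steps renormalised so each day's mean hourly step equals its latent
    level) and inverse-projected to WGS84. Fixes are dropped independently
    at ``cfg.missing_rate``. Returns (tracks, ground_truth) where
    ground_truth has columns individual_id, date, age, state, speed_kmh.
    """
    levels = levels if levels is not None else simulate_day_levels(cfg)
    lat_min, lat_max, lon_min, lon_max = cfg.extent
    proj = AzimuthalEquidistant(0.5 * (lat_min + lat_max), 0.5 * (lon_min + lon_max))
    # keep walkers inside a box slightly smaller than the raster extent
    (x0, y0) = proj.forward(lat_min, lon_min)
    (x1, y1) = proj.forward(lat_max, lon_max)
    xlo, xhi = min(x0, x1) + 2, max(x0, x1) - 2
    ylo, yhi = min(y0, y1) + 2, max(y0, y1) - 2

    tracks: dict[str, Track] = {}
    for k, (ind, g) in enumerate(levels.groupby("individual_id", sort=True)):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 43, k]))
        g = g.sort_values("date")
        n_days = len(g)
        x = rng.uniform(xlo + 5, xhi - 5)
        y = rng.uniform(ylo + 5, yhi - 5)
        heading = rng.uniform(-math.pi, math.pi)
        # anchor fix one hour before the first day's first step
        first_utc = (pd.Timestamp(g["date"].iloc[0], tz="UTC")
                     - pd.Timedelta(hours=3) - pd.Timedelta(hours=1))
        times = [first_utc]
        xs, ys = [x], [y]
        for d in range(n_days):
            lvl = float(g["speed_kmh"].iloc[d])
            raw = rng.gamma(cfg.step_shape, 1.0, size=24)
            steps = raw / raw.mean() * lvl  # km per 1-h step
            turns = rng.normal(0.0, cfg.turn_sd_rad, size=24)
            day_utc = pd.Timestamp(g["date"].iloc[d], tz="UTC") - pd.Timedelta(hours=3)
            for h in range(24):
                heading = heading + turns[h]
                # soft containment: head back towards the box centre
                if not (xlo < x < xhi and ylo < y < yhi):
                    heading = math.atan2(0.5 * (ylo + yhi) - y,
                                         0.5 * (xlo + xhi) - x)
                x += steps[h] * math.cos(heading)
                y += steps[h] * math.sin(heading)
                times.append(day_utc + pd.Timedelta(hours=h))
                xs.append(x)
                ys.append(y)
        lat, lon = proj.inverse(np.array(xs), np.array(ys))
        fixes = pd.DataFrame({"timestamp": times, "lat": lat, "lon": lon,
                              "interpolated": False})
        if cfg.missing_rate > 0:
            keep = rng.random(len(fixes)) >= cfg.missing_rate
            keep[0] = True
            fixes = fixes[keep].reset_index(drop=True)
        tracks[ind] = Track(individual_id=ind, fixes=fixes)
    return tracks, levels


def simulate_observations(ground_truth: pd.DataFrame, rate: float,
                          seed: int = 0,
                          one_signal_fraction: float = 0.0) -> pd.DataFrame:
    """Bernoulli daily sightings with field signal counts.

    Sighted musth days carry 2-3 signals, non-musth days 0; a configurable
    fraction of sightings is degraded to a single (ambiguous) signal so
    downstream exclusion logic is exercised. Columns: id, date, n_signals.
    """
    if not (0.0 < rate <= 1.0):
        raise ValueError("rate must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 61]))
    rows = []
    for row in ground_truth.itertuples(index=False):
        if rng.random() >= rate:
            continue
        if rng.random() < one_signal_fraction:
            n = 1
        elif row.state == "musth":
            n = int(rng.integers(2, 4))
        else:
            n = 0
        rows.append({"id": row.individual_id, "date": row.date, "n_signals": n})
    return pd.DataFrame(rows, columns=["id", "date", "n_signals"])


# ---------------------------------------------------------------------------
# direct HMM windows (for sampler validation)

def simulate_hmm_window(T: int = 240, bout: tuple[int, int] | None = (100, 160),
                        beta: tuple = (-1.2, -0.4, -1.2),
                        sigma: tuple = (0.2, 0.2, 0.2),
                        missing: float = 0.0, seed: int = 0,
                        individual_id: str = "sim") -> tuple[HmmWindow, np.ndarray]:
    """Draw a window straight from the ordered-HMM emission model.

    ``bout`` gives the (first, last) day index in state 2 (None for a
    window that stays in state 1). Returns (window, true_states).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 83]))
    states = np.zeros(T, int)
    if bout is not None:
        t1, t2 = bout
        states[t1:t2 + 1] = 1
        states[t2 + 1:] = 2
    beta = np.asarray(beta, float)
    sigma = np.asarray(sigma, float)
    y = beta[states] + sigma[states] * rng.normal(size=T)
    observed = rng.random(T) >= missing
    dates = [dt.date(2012, 1, 1) + dt.timedelta(days=i) for i in range(T)]
    return (HmmWindow(individual_id=individual_id, y=np.where(observed, y, 0.0),
                      observed=observed, dates=dates), states)
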