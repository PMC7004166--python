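"""Data model and I/O for GPS fixes, musth observations, and the study roster.

Timestamps are stored in UTC. Calendar days everywhere downstream are
defined in East Africa Time (UTC+3), the study-site timezone, so that a
"day" of movement corresponds to a local day-night cycle.

Musth labelling follows the field protocol: a bull is scored on three
signals (temporal gland swelling, temporal gland secretion, urine
dribbling). Observations with 2-3 signals are labelled ``musth``, 0
signals ``non_musth``, and single-signal observations are ``excluded``
from analysis (retained but flagged).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EAT_OFFSET = pd.Timedelta(hours=3)
#: Fixed birthday anchor: bulls age up on 31 August (dry-season midpoint).
BIRTHDAY_MONTH, BIRTHDAY_DAY = 8, 31

LABEL_MUSTH = "musth"
LABEL_NON_MUSTH = "non_musth"
LABEL_EXCLUDED = "excluded"


class ValidationError(ValueError):
    """Raised for rows that violate the data-model invariants."""


@dataclass
class Track:
    """One individual's fixes, time-sorted, timestamps unique."""

    individual_id: str
    fixes: pd.DataFrame  # columns: timestamp (tz-aware UTC), lat, lon, interpolated

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class RosterEntry:
    name: str
    min_age: int
    max_age: int
    obs_days_nonmusth: int
    obs_days_musth: int
    total_days_nonmusth: int
    total_days_musth: int

    def __post_init__(self):
        if self.min_age > self.max_age:
            raise ValidationError(f"{self.name}: min_age > max_age")
        for f in ("obs_days_nonmusth", "obs_days_musth",
                  "total_days_nonmusth", "total_days_musth"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{self.name}: negative count {f}")


@dataclass
class RosterSummary:
    n_individuals: int
    min_age: int
    max_age: int
    obs_days_nonmusth: int
    obs_days_musth: int
    total_days_nonmusth: int
    total_days_musth: int


def eat_date(timestamp: pd.Timestamp) -> dt.date:
    """Calendar date of a UTC instant in East Africa Time (UTC+3)."""
    return (pd.Timestamp(timestamp) + EAT_OFFSET).date()


def age_at(date: dt.date, birth_year: int) -> int:
    """Integer age in years on `date` under the fixed 31-August birthday."""
    age = date.year - birth_year
    if (date.month, date.day) < (BIRTHDAY_MONTH, BIRTHDAY_DAY):
        age -= 1
    return age


def _validate_coords(lat: float, lon: float, line: int | None = None) -> None:
    where = f" (line {line})" if line is not None else ""
    if not (-90.0 <= lat <= 90.0):
        raise ValidationError(f"latitude {lat} out of range [-90, 90]{where}")
    if not (-180.0 < lon <= 180.0):
        raise ValidationError(f"longitude {lon} out of range (-180, 180]{where}")


def read_fixes(path) -> dict[str, Track]:
    """Read a fixes CSV (columns id, timestamp, lat, lon[, interpolated]).

    Returns tracks keyed by individual id, each sorted by time with
    duplicate timestamps collapsed (first kept, with a warning). Unsorted
    input is sorted silently; malformed rows raise :class:`ValidationError`
    with the 1-based line number.
    """
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "timestamp", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"fixes CSV missing columns: {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    bad = ts.isna() | df["id"].isna() | df["lat"].isna() | df["lon"].isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
        raise ValidationError(f"malformed fix row at line {line}")
    for i, (la, lo) in enumerate(zip(df["lat"], df["lon"])):
        if not (-90.0 <= la <= 90.0) or not (-180.0 < lo <= 180.0):
            _validate_coords(la, lo, line=i + 2)
    df = df.assign(timestamp=ts)
    if "interpolated" not in df.columns:
        df["interpolated"] = False
    df["interpolated"] = df["interpolated"].astype(bool)

    tracks: dict[str, Track] = {}
    for ind, g in df.groupby("id", sort=True):
        g = g.sort_values("timestamp", kind="mergesort")
        dup = g["timestamp"].duplicated(keep="first")
        if dup.any():
            logger.warning("%s: %d duplicate timestamps collapsed (first kept)",
                           ind, int(dup.sum()))
            g = g[~dup]
        fixes = g[["timestamp", "lat", "lon", "interpolated"]].reset_index(drop=True)
        tracks[str(ind)] = Track(individual_id=str(ind), fixes=fixes)
    return tracks


def write_fixes(tracks: dict[str, Track] | Iterable[Track], path) -> None:
    """Write tracks to the canonical fixes CSV.

    Canonical form: ids in sorted order, timestamps ISO-8601 ``+00:00``,
    coordinates to 6 decimal places, interpolated as 0/1. Reading then
    writing a canonical file reproduces it byte-for-byte.
    """
    if isinstance(tracks, dict):
        tracks = [tracks[k] for k in sorted(tracks)]
    with open(path, "w", newline="") as fh:
        fh.write("id,timestamp,lat,lon,interpolated\n")
        for tr in tracks:
            for row in tr.fixes.itertuples(index=False):
                ts = row.timestamp.strftime("%Y-%m-%dT%H:%M:%S+00:00")
                fh.write(f"{tr.individual_id},{ts},{row.lat:.6f},{row.lon:.6f},"
                         f"{int(row.interpolated)}\n")


def label_observations(raw: pd.DataFrame, prelabelled: bool = False) -> pd.DataFrame:
    """Label field sightings as musth / non_musth / excluded.

    `raw` needs columns ``id, date, n_signals`` (signal count 0-3), or
    ``id, date, label`` with ``prelabelled=True`` for exports that carry a
    ready-made musth/non-musth label. Excluded (single-signal) records are
    retained but flagged so downstream stages skip them.
    """
    out = raw.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out = out.rename(columns={"id": "individual_id"})
    if prelabelled:
        if "label" not in out.columns:
            raise ValidationError("prelabelled observations need a 'label' column")
        ok = out["label"].isin([LABEL_MUSTH, LABEL_NON_MUSTH, LABEL_EXCLUDED])
        if not ok.all():
            raise ValidationError(
                f"unknown labels: {sorted(out.loc[~ok, 'label'].unique())}")
        out["n_signals"] = pd.NA
        return out[["individual_id", "date", "n_signals", "label"]]
    n = pd.to_numeric(out["n_signals"], errors="coerce")
    if n.isna().any() or (n < 0).any() or (n > 3).any() or (n != n.round()).any():
        raise ValidationError("n_signals must be an integer in 0..3")
    n = n.astype(int)
    label = np.where(n >= 2, LABEL_MUSTH,
                     np.where(n == 1, LABEL_EXCLUDED, LABEL_NON_MUSTH))
    out["n_signals"] = n
    out["label"] = label
    return out[["individual_id", "date", "n_signals", "label"]]


def load_roster(path=None) -> list[RosterEntry]:
    """Load the study roster (packaged transcription of the 25-bull sample
    table by default, or a CSV in the same dialect)."""
    if path is None:
        with resources.files("musthtrack.data").joinpath("roster.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    return [RosterEntry(**{k: (str(v) if k == "name" else int(v))
                           for k, v in row.items()})
            for row in df.to_dict("records")]


def tally_roster(roster: list[RosterEntry]) -> RosterSummary:
    """Column sums, individual count and age extremes over a roster."""
    if not roster:
        raise ValidationError("empty roster")
    return RosterSummary(
        n_individuals=len(roster),
        min_age=min(e.min_age for e in roster),
        max_age=max(e.max_age for e in roster),
        obs_days_nonmusth=sum(e.obs_days_nonmusth for e in roster),
        obs_days_musth=sum(e.obs_days_musth for e in roster),
        total_days_nonmusth=sum(e.total_days_nonmusth for e in roster),
        total_days_musth=sum(e.total_days_musth for e in roster),
    )
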