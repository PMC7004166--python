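"""Track regularisation: hourly downsampling, CTCRW gap filling, day QC.

Collars recorded at 15/30/60-min intervals; all tracks are reduced to one
fix per hour on the hour (nearest fix within +/-5 min, timestamp snapped to
the hour). Gaps of at most 4 h are filled with positions predicted by the
fitted continuous-time correlated random walk; longer gaps stay open. A
calendar day (East Africa Time) enters the analysis only if it has at
least 20 hourly fixes and no gap longer than 4 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctcrw import CtcrwFit, fit_ctcrw_xy, kalman_smooth_positions
from .geo import AzimuthalEquidistant
from .trackio import EAT_OFFSET, Track

DEFAULT_SNAP_TOLERANCE_MIN = 5
DEFAULT_MAX_GAP_HOURS = 4
DEFAULT_MIN_FIXES_PER_DAY = 20


@dataclass
class RegularTrack:
    """Hourly track plus its per-day QC table.

    ``fixes``: timestamp (UTC, on the hour), lat, lon, interpolated.
    ``qc``: date (EAT), n_fixes, max_gap_h, included.
    """

    individual_id: str
    fixes: pd.DataFrame
    qc: pd.DataFrame = field(default_factory=pd.DataFrame)


def downsample_hourly(track: Track,
                      snap_tolerance_min: int = DEFAULT_SNAP_TOLERANCE_MIN) -> Track:
    """Keep the fix nearest each top-of-hour within the snap tolerance.

    Kept fixes have their timestamp snapped to the hour; hours with no fix
    inside the tolerance become gaps. Already-hourly tracks pass through
    (idempotent). No missing hours are fabricated here.
    """
    df = track.fixes
    if df.empty:
        return Track(track.individual_id, df.copy())
    ts = df["timestamp"]
    nearest_hour = ts.dt.round("h")
    offset_min = (ts - nearest_hour).dt.total_seconds().abs() / 60.0
    cand = df.assign(_hour=nearest_hour, _off=offset_min)
    cand = cand[cand["_off"] <= snap_tolerance_min]
    cand = cand.sort_values(["_hour", "_off"], kind="mergesort")
    cand = cand.drop_duplicates("_hour", keep="first")
    out = (cand.assign(timestamp=cand["_hour"])
           .drop(columns=["_hour", "_off"])
           .sort_values("timestamp", kind="mergesort")
           .reset_index(drop=True))
    return Track(track.individual_id, out)


def fit_ctcrw(track: Track,
              projection: AzimuthalEquidistant | None = None) -> CtcrwFit:
    """ML fit of the integrated-OU movement model on the projected plane.

    The projection defaults to an azimuthal equidistant plane centred on
    the track centroid. Parameters are shared between the two axes.
    """
    df = track.fixes
    proj = projection or AzimuthalEquidistant.for_points(df["lat"], df["lon"])
    x, y = proj.forward(df["lat"].to_numpy(), df["lon"].to_numpy())
    t0 = df["timestamp"].iloc[0]
    t = (df["timestamp"] - t0).dt.total_seconds().to_numpy() / 3600.0
    return fit_ctcrw_xy(x, y, t)


def interpolate_gaps(track: Track, fit: CtcrwFit | None,
                     max_gap_hours: int = DEFAULT_MAX_GAP_HOURS,
                     fallback_linear: bool = True,
                     projection: AzimuthalEquidistant | None = None,
                     min_fixes_per_day: int = DEFAULT_MIN_FIXES_PER_DAY) -> RegularTrack:
    """Fill short gaps in an hourly track with CTCRW-smoothed positions.

    Missing top-of-hours strictly inside gaps of at most ``max_gap_hours``
    get Kalman-smoothed predictions flagged ``interpolated``; longer gaps
    are left open. If no usable fit is available and ``fallback_linear``,
    positions are interpolated linearly in time instead. Observed fixes
    are never altered. The returned track carries the day-QC table.
    """
    df = track.fixes.reset_index(drop=True)
    if df.empty:
        return RegularTrack(track.individual_id, df.copy(), _qc_table(df))
    ts = df["timestamp"]
    gaps_h = ts.diff().dt.total_seconds().to_numpy() / 3600.0
    insert_times: list[pd.Timestamp] = []
    for i in range(1, len(ts)):
        g = gaps_h[i]
        if 1.0 < g <= max_gap_hours:
            t = ts.iloc[i - 1] + pd.Timedelta(hours=1)
            while t < ts.iloc[i]:
                insert_times.append(t)
                t += pd.Timedelta(hours=1)
    if insert_times:
        proj = projection or AzimuthalEquidistant.for_points(df["lat"], df["lon"])
        x, y = proj.forward(df["lat"].to_numpy(), df["lon"].to_numpy())
        t0 = ts.iloc[0]
        t_obs = (ts - t0).dt.total_seconds().to_numpy() / 3600.0
        t_q = np.array([(t - t0).total_seconds() / 3600.0 for t in insert_times])
        usable = fit is not None and fit.converged and not fit.boundary
        if usable:
            xq, yq = kalman_smooth_positions(x, y, t_obs, t_q,
                                             fit.theta_per_h, fit.zeta_kmh)
        elif fallback_linear:
            xq = np.interp(t_q, t_obs, x)
            yq = np.interp(t_q, t_obs, y)
        else:
            raise ValueError("no CTCRW fit and linear fallback disabled")
        lat_q, lon_q = proj.inverse(xq, yq)
        add = pd.DataFrame({"timestamp": insert_times, "lat": lat_q,
                            "lon": lon_q, "interpolated": True})
        df = (pd.concat([df, add], ignore_index=True)
              .sort_values("timestamp", kind="mergesort")
              .reset_index(drop=True))
    qc = _qc_table(df, max_gap_hours=max_gap_hours,
                   min_fixes_per_day=min_fixes_per_day)
    return RegularTrack(track.individual_id, df, qc)


def _qc_table(df: pd.DataFrame,
              max_gap_hours: int = DEFAULT_MAX_GAP_HOURS,
              min_fixes_per_day: int = DEFAULT_MIN_FIXES_PER_DAY) -> pd.DataFrame:
    """Per-EAT-day fix counts and the largest gap touching the day.

    A gap between consecutive fixes is charged to every day overlapping
    the open interval between them, so an overnight hole counts against
    both adjacent days.
    """
    cols = ["date", "n_fixes", "max_gap_h", "included"]
    if df.empty:
        return pd.DataFrame(columns=cols)
    local = df["timestamp"] + EAT_OFFSET
    dates = local.dt.date
    counts = dates.value_counts().sort_index()
    max_gap = {d: 0.0 for d in counts.index}
    ts = df["timestamp"].to_numpy()
    for i in range(1, len(ts)):
        g = (ts[i] - ts[i - 1]) / np.timedelta64(1, "s") / 3600.0
        d0 = (pd.Timestamp(ts[i - 1]) + EAT_OFFSET).date()
        d1 = (pd.Timestamp(ts[i]) + EAT_OFFSET).date()
        d = d0
        while d <= d1:
            if d in max_gap:
                max_gap[d] = max(max_gap[d], g)
            d += pd.Timedelta(days=1).to_pytimedelta()
    rows = [{"date": d, "n_fixes": int(counts[d]), "max_gap_h": float(max_gap[d]),
             "included": bool(counts[d] >= min_fixes_per_day
                              and max_gap[d] <= max_gap_hours)}
            for d in counts.index]
    return pd.DataFrame(rows, columns=cols)


def qc_days(rt: RegularTrack,
            max_gap_hours: int = DEFAULT_MAX_GAP_HOURS,
            min_fixes_per_day: int = DEFAULT_MIN_FIXES_PER_DAY) -> pd.DataFrame:
    """Recompute the day-inclusion table for a regularised track."""
    return _qc_table(rt.fixes, max_gap_hours=max_gap_hours,
                     min_fixes_per_day=min_fixes_per_day)


def regularize(track: Track,
               snap_tolerance_min: int = DEFAULT_SNAP_TOLERANCE_MIN,
               max_gap_hours: int = DEFAULT_MAX_GAP_HOURS,
               min_fixes_per_day: int = DEFAULT_MIN_FIXES_PER_DAY,
               fallback_linear: bool = True) -> RegularTrack:
    """Convenience pipeline: downsample, fit CTCRW, interpolate, QC."""
    hourly = downsample_hourly(track, snap_tolerance_min=snap_tolerance_min)
    fit = None
    if len(hourly) >= 48:
        try:
            fit = fit_ctcrw(hourly)
        except Exception:
            fit = None
    return interpolate_gaps(hourly, fit, max_gap_hours=max_gap_hours,
                            fallback_linear=fallback_linear,
                            min_fixes_per_day=min_fixes_per_day)
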