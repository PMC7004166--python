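"""Daily movement statistics: mean speed, 95% MCP range, sinuosity.

Speed steps use great-circle (haversine) distance over elapsed time
between consecutive fixes; the step that crosses local midnight belongs
to the day in which it ends. The daily range is the area of the minimum
convex polygon after peeling the 5% of fixes farthest from the day's
centroid on a local planar projection. Sinuosity is Benhamou's corrected
index; it is computed but optional downstream because it is nearly
collinear with speed and range in this kind of data.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .geo import AzimuthalEquidistant, haversine_km
from .preprocess import RegularTrack
from .trackio import EAT_OFFSET

__all__ = ["haversine_km", "daily_mean_speed", "mcp_km2", "sinuosity",
           "compute_daily_metrics"]


def daily_mean_speed(day_fixes: pd.DataFrame) -> float:
    """Mean over consecutive-fix steps of (great-circle km / elapsed h).

    ``day_fixes`` must be time-sorted and include, when available, the
    last fix of the previous day as its first row so the midnight-crossing
    step is counted (`compute_daily_metrics` arranges this).
    """
    if len(day_fixes) < 2:
        raise ValueError("daily mean speed needs at least 2 fixes")
    lat = day_fixes["lat"].to_numpy()
    lon = day_fixes["lon"].to_numpy()
    dt_h = day_fixes["timestamp"].diff().dt.total_seconds().to_numpy()[1:] / 3600.0
    d = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    return float(np.mean(np.asarray(d) / dt_h))


def mcp_km2(day_fixes: pd.DataFrame, percent: float = 95.0) -> float:
    """Minimum-convex-polygon area (km^2) after the percent peel.

    Fixes are projected to a local azimuthal equidistant plane; the
    ceil((1 - percent/100) * n) points farthest from the arithmetic
    centroid are removed (ties: earlier timestamp removed first), and the
    convex hull area of the remainder is returned. Collinear or identical
    points give area 0.
    """
    n = len(day_fixes)
    if n < 5:
        raise ValueError("MCP needs at least 5 fixes")
    proj = AzimuthalEquidistant.for_points(day_fixes["lat"], day_fixes["lon"])
    x, y = proj.forward(day_fixes["lat"].to_numpy(), day_fixes["lon"].to_numpy())
    n_drop = math.ceil((1.0 - percent / 100.0) * n)
    if n_drop > 0:
        cx, cy = x.mean(), y.mean()
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        # farthest first; among ties the earlier timestamp goes first
        order = np.lexsort((np.arange(n), -d2))
        keep = np.sort(order[n_drop:])
        x, y = x[keep], y[keep]
    hull = MultiPoint(list(zip(x, y))).convex_hull
    return float(getattr(hull, "area", 0.0))


def sinuosity(day_fixes: pd.DataFrame) -> float:
    """Benhamou's corrected sinuosity index, units 1/sqrt(km).

    S = 2 [ p ( (1+c)/(1-c) + b^2 ) ]^(-1/2) with p the mean step length
    (km), c the mean cosine of turning angles and b the coefficient of
    variation of step length. A perfectly straight path (c -> 1) has
    sinuosity 0.
    """
    if len(day_fixes) < 3:
        raise ValueError("sinuosity needs at least 3 fixes")
    proj = AzimuthalEquidistant.for_points(day_fixes["lat"], day_fixes["lon"])
    x, y = proj.forward(day_fixes["lat"].to_numpy(), day_fixes["lon"].to_numpy())
    dx, dy = np.diff(x), np.diff(y)
    lengths = np.hypot(dx, dy)
    if np.any(lengths == 0):
        dx, dy = dx[lengths > 0], dy[lengths > 0]
        lengths = lengths[lengths > 0]
    if len(lengths) < 2:
        return 0.0
    headings = np.arctan2(dy, dx)
    turns = np.diff(headings)
    c = float(np.mean(np.cos(turns)))
    p = float(np.mean(lengths))
    b = float(np.std(lengths) / p)
    if c >= 1.0 - 1e-12:
        return 0.0
    return float(2.0 / math.sqrt(p * ((1.0 + c) / (1.0 - c) + b * b)))


def compute_daily_metrics(rt: RegularTrack, mcp_percent: float = 95.0) -> pd.DataFrame:
    """Per-day metrics for every QC-included day of a regularised track.

    Returns columns: individual_id, date, n_fixes, mean_speed_kmh,
    mcp95_km2, sinuosity. Interpolated fixes participate like observed
    ones. The speed of the step crossing midnight is charged to the day
    the step ends in; the MCP and sinuosity use only the day's own fixes.
    """
    df = rt.fixes
    qc = rt.qc if not rt.qc.empty else None
    if df.empty:
        return pd.DataFrame(columns=["individual_id", "date", "n_fixes",
                                     "mean_speed_kmh", "mcp95_km2", "sinuosity"])
    dates = (df["timestamp"] + EAT_OFFSET).dt.date
    included = set(qc.loc[qc["included"], "date"]) if qc is not None else set(dates)
    rows = []
    for d, g in df.groupby(dates):
        if d not in included:
            continue
        idx0 = g.index[0]
        day = g
        if idx0 > 0:
            prev = df.loc[idx0 - 1]
            # only bridge a real hourly step, not a long gap
            if (g["timestamp"].iloc[0] - prev["timestamp"]).total_seconds() <= 3600 * 4:
                day = pd.concat([df.loc[[idx0 - 1]], g])
        rows.append({
            "individual_id": rt.individual_id,
            "date": d,
            "n_fixes": int(len(g)),
            "mean_speed_kmh": daily_mean_speed(day),
            "mcp95_km2": mcp_km2(g, percent=mcp_percent),
            "sinuosity": sinuosity(g),
        })
    return pd.DataFrame(rows)
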