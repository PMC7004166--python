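"""Environmental covariates: terrain slope and ruggedness, NDVI time
slices, distance to water, protected-area membership; per-fix sampling,
per-day averaging, and model-input standardization.

Rasters are ESRI ASCII grids (plain text with ncols/nrows, lower-left
corner and cell size in decimal degrees); vector features are GeoJSON
read into shapely geometries. NDVI comes as 16-day composites whose
filenames carry the window start date (``ndvi_YYYY-MM-DD.asc``).
"""

from __future__ import annotations

import datetime as dt
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.ops import unary_union

from .geo import EARTH_RADIUS_KM, AzimuthalEquidistant
from .preprocess import RegularTrack
from .trackio import EAT_OFFSET

KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0
NDVI_WINDOW_DAYS = 16

COVARIATE_COLUMNS = ["ndvi", "slope", "vrm", "dist_water", "protected"]


# ---------------------------------------------------------------------------
# raster container and I/O

@dataclass
class AsciiGrid:
    """North-up raster on a regular lon/lat grid (ESRI ASCII dialect).

    ``values[0, 0]`` is the north-west cell; ``xll, yll`` the lower-left
    corner of the grid in degrees; ``cellsize`` in degrees.
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """Row/col of the cell containing the point; raises if outside."""
        col = int(math.floor((lon - self.xll) / self.cellsize))
        row_from_bottom = int(math.floor((lat - self.yll) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({lat}, {lon}) outside raster")
        return row, col

    def sample(self, lat: float, lon: float) -> float:
        r, c = self.cell_index(lat, lon)
        v = float(self.values[r, c])
        return math.nan if v == self.nodata else v


def read_ascii_grid(path) -> AsciiGrid:
    with open(path) as fh:
        header = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(val)
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh).reshape(int(header["nrows"]), int(header["ncols"]))
    return AsciiGrid(values=values, xll=header["xllcorner"], yll=header["yllcorner"],
                     cellsize=header["cellsize"],
                     nodata=header.get("nodata_value", -9999.0))


def write_ascii_grid(grid: AsciiGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\nnrows {grid.nrows}\n"
                 f"xllcorner {grid.xll!r}\nyllcorner {grid.yll!r}\n"
                 f"cellsize {grid.cellsize!r}\nNODATA_value {grid.nodata!r}\n")
        np.savetxt(fh, grid.values, fmt="%.6g")


# ---------------------------------------------------------------------------
# terrain derivatives

def _cell_size_m(grid: AsciiGrid) -> tuple[float, float]:
    """(dx, dy) metres of one cell at the grid's central latitude."""
    lat_mid = grid.yll + 0.5 * grid.nrows * grid.cellsize
    dy = grid.cellsize * KM_PER_DEG * 1000.0
    dx = dy * math.cos(math.radians(lat_mid))
    return dx, dy


def _horn_gradients(z: np.ndarray, dx: float, dy: float):
    """Horn's eight-neighbour finite differences (edge-padded)."""
    zp = np.pad(z, 1, mode="edge")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2]; f = zp[1:-1, 2:]
    g = zp[2:, :-2]; h = zp[2:, 1:-1]; i = zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dx)
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * dy)  # +y = north
    return dzdx, dzdy


def slope_deg(grid: AsciiGrid) -> AsciiGrid:
    """Slope in degrees [0, 90] by Horn's method; edges use padded values."""
    dx, dy = _cell_size_m(grid)
    dzdx, dzdy = _horn_gradients(grid.values, dx, dy)
    s = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return AsciiGrid(values=s, xll=grid.xll, yll=grid.yll,
                     cellsize=grid.cellsize, nodata=grid.nodata)


def vrm(grid: AsciiGrid, window: int = 3) -> AsciiGrid:
    """Vector ruggedness measure in [0, 1] (Sappington et al. construction).

    Each cell contributes a unit surface normal decomposed with its slope
    and aspect; VRM = 1 - |mean resultant vector| over the moving window.
    Flat and uniformly inclined terrain both give 0.
    """
    dx, dy = _cell_size_m(grid)
    dzdx, dzdy = _horn_gradients(grid.values, dx, dy)
    slope_r = np.arctan(np.hypot(dzdx, dzdy))
    aspect = np.arctan2(dzdy, dzdx)  # any consistent convention works
    zc = np.cos(slope_r)
    xyc = np.sin(slope_r)
    xc = xyc * np.cos(aspect)
    yc = xyc * np.sin(aspect)
    k = np.ones((window, window))
    from scipy.ndimage import convolve
    n = convolve(np.ones_like(zc), k, mode="nearest")
    rx = convolve(xc, k, mode="nearest")
    ry = convolve(yc, k, mode="nearest")
    rz = convolve(zc, k, mode="nearest")
    v = 1.0 - np.sqrt(rx ** 2 + ry ** 2 + rz ** 2) / n
    return AsciiGrid(values=np.clip(v, 0.0, 1.0), xll=grid.xll, yll=grid.yll,
                     cellsize=grid.cellsize, nodata=grid.nodata)


# ---------------------------------------------------------------------------
# covariate stack

@dataclass
class CovariateStack:
    elevation: AsciiGrid
    ndvi: dict[dt.date, AsciiGrid]            # keyed by 16-day window start
    water: object                             # shapely geometry (union)
    protected: object                         # shapely geometry (union)
    slope: AsciiGrid = None
    vrm: AsciiGrid = None

    def __post_init__(self):
        if self.slope is None:
            self.slope = slope_deg(self.elevation)
        if self.vrm is None:
            self.vrm = vrm(self.elevation)

    def ndvi_slice(self, date: dt.date) -> AsciiGrid:
        """The composite whose 16-day validity window contains `date`."""
        starts = sorted(self.ndvi)
        for s in reversed(starts):
            if s <= date < s + dt.timedelta(days=NDVI_WINDOW_DAYS):
                return self.ndvi[s]
        raise KeyError(f"no NDVI composite covers {date}")


def load_stack(directory) -> CovariateStack:
    d = Path(directory)
    elev = read_ascii_grid(d / "elevation.asc")
    ndvi = {}
    for p in sorted(d.glob("ndvi_*.asc")):
        m = re.match(r"ndvi_(\d{4}-\d{2}-\d{2})\.asc$", p.name)
        if m:
            ndvi[dt.date.fromisoformat(m.group(1))] = read_ascii_grid(p)
    water = _read_geojson(d / "water.geojson")
    protected = _read_geojson(d / "protected.geojson")
    return CovariateStack(elevation=elev, ndvi=ndvi, water=water, protected=protected)


def _read_geojson(path):
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    return unary_union([shape(f["geometry"]) for f in feats])


def write_geojson(geoms, path) -> None:
    feats = [{"type": "Feature", "properties": {},
              "geometry": json.loads(json.dumps(g.__geo_interface__))}
             for g in (geoms if isinstance(geoms, (list, tuple)) else [geoms])]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# sampling and aggregation

def sample_covariates(rt: RegularTrack, stack: CovariateStack) -> pd.DataFrame:
    """Nearest-cell raster values plus water distance and protected flag
    for every fix. Fixes outside the rasters get missing covariates."""
    df = rt.fixes
    proj = AzimuthalEquidistant.for_points(df["lat"], df["lon"])
    wx_geom = _project_geometry(stack.water, proj)
    pa_geom = _project_geometry(stack.protected, proj)
    rows = []
    for row in df.itertuples(index=False):
        date = (row.timestamp + EAT_OFFSET).date()
        rec = {"individual_id": rt.individual_id, "timestamp": row.timestamp,
               "date": date}
        try:
            rec["slope"] = stack.slope.sample(row.lat, row.lon)
            rec["vrm"] = stack.vrm.sample(row.lat, row.lon)
            rec["ndvi"] = stack.ndvi_slice(date).sample(row.lat, row.lon)
        except (ValueError, KeyError):
            rec["slope"] = rec["vrm"] = rec["ndvi"] = math.nan
        x, y = proj.forward(row.lat, row.lon)
        p = Point(float(x), float(y))
        rec["dist_water"] = float(p.distance(wx_geom))  # km on the local plane
        rec["protected"] = float(pa_geom.contains(p) or pa_geom.touches(p))
        rows.append(rec)
    return pd.DataFrame(rows)


def _project_geometry(geom, proj: AzimuthalEquidistant):
    from shapely.ops import transform

    def f(lon, lat, z=None):
        x, y = proj.forward(np.asarray(lat), np.asarray(lon))
        return x, y

    return transform(f, geom)


def daily_covariate_means(per_fix: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic per-day means; protected rounded to the nearest binary
    (mean of exactly 0.5 rounds up, i.e. counts as protected)."""
    grp = per_fix.groupby(["individual_id", "date"], as_index=False)
    out = grp[COVARIATE_COLUMNS].mean()
    out["protected"] = (out["protected"] >= 0.5).astype(float)
    return out


# ---------------------------------------------------------------------------
# standardization

AGE_CENTER_YEARS = 35.0  # bulls start showing clear musth periods around 35


@dataclass
class StandardizationParams:
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    age_center: float = AGE_CENTER_YEARS

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c, m in self.means.items():
            out[c] = out[c] * self.sds[c] + m
        if "age" in out.columns:
            out["age"] = out["age"] + self.age_center
        return out


def standardize(df: pd.DataFrame, columns: list[str] | None = None
                ) -> tuple[pd.DataFrame, StandardizationParams]:
    """(x - mean)/SD over the pooled analysis set (sample SD, n-1).

    The ``age`` column, when present, is centred at 35 years but kept in
    years (not scaled). Computed once over all individuals' included
    days, never per individual.
    """
    if columns is None:
        columns = [c for c in COVARIATE_COLUMNS if c != "protected"
                   and c in df.columns]
    out = df.copy()
    params = StandardizationParams()
    for c in columns:
        m = float(df[c].mean())
        s = float(df[c].std(ddof=1))
        if not s > 1e-12 * max(abs(m), 1.0):
            raise ValueError(f"zero-variance column: {c}")
        out[c] = (df[c] - m) / s
        params.means[c] = m
        params.sds[c] = s
    if "age" in out.columns:
        out["age"] = df["age"] - params.age_center
    return out, params
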