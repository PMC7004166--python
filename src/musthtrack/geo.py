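"""Spherical geometry: great-circle distance and a local azimuthal equidistant projection.

All distances are in kilometres on a sphere of radius ``EARTH_RADIUS_KM``
(the IUGG mean Earth radius). The azimuthal equidistant projection is the
spherical form, adequate for study areas a few hundred kilometres across:
distances from the projection centre are exact and distances between
nearby points are accurate to second order in (extent / Earth radius).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle (orthodromic) distance in km via the haversine formula.

    Accepts scalars or numpy arrays (broadcast). Coordinates in decimal
    degrees, WGS84 treated as spherical.
    """
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards against rounding for antipodal points
    c = 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    d = radius_km * c
    if np.ndim(d) == 0:
        return float(d)
    return d


class AzimuthalEquidistant:
    """Local azimuthal equidistant projection centred on (lat0, lon0).

    ``forward`` maps degrees to planar (x, y) in km; ``inverse`` maps back.
    East is +x, north is +y.
    """

    def __init__(self, lat0: float, lon0: float, radius_km: float = EARTH_RADIUS_KM):
        self.lat0 = float(lat0)
        self.lon0 = float(lon0)
        self.radius_km = float(radius_km)
        self._sin0 = np.sin(np.radians(lat0))
        self._cos0 = np.cos(np.radians(lat0))

    def forward(self, lat, lon):
        phi = np.radians(np.asarray(lat, dtype=float))
        dlam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        sinp, cosp = np.sin(phi), np.cos(phi)
        cosc = np.clip(self._sin0 * sinp + self._cos0 * cosp * np.cos(dlam), -1.0, 1.0)
        c = np.arccos(cosc)
        sinc = np.sin(c)
        # k = c/sin(c) -> 1 at the centre
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(sinc > 1e-12, c / np.where(sinc > 1e-12, sinc, 1.0), 1.0)
        x = self.radius_km * k * cosp * np.sin(dlam)
        y = self.radius_km * k * (self._cos0 * sinp - self._sin0 * cosp * np.cos(dlam))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / self.radius_km
        y = np.asarray(y, dtype=float) / self.radius_km
        rho = np.hypot(x, y)
        c = rho
        sinc, cosc = np.sin(c), np.cos(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            fy = np.where(rho > 1e-12, y / np.where(rho > 1e-12, rho, 1.0), 0.0)
            fx = np.where(rho > 1e-12, x / np.where(rho > 1e-12, rho, 1.0), 0.0)
        phi = np.arcsin(np.clip(cosc * self._sin0 + fy * sinc * self._cos0, -1.0, 1.0))
        lam = np.arctan2(
            fx * sinc, np.where(rho > 1e-12, cosc * self._cos0 - fy * sinc * self._sin0, 1.0)
        )
        lat = np.degrees(phi)
        lon = self.lon0 + np.degrees(np.where(rho > 1e-12, lam, 0.0))
        return lat, lon

    @classmethod
    def for_points(cls, lat, lon) -> "AzimuthalEquidistant":
        """Projection centred on the arithmetic centroid of the points."""
        return cls(float(np.mean(lat)), float(np.mean(lon)))
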