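"""Great-circle geometry for the distance covariate.

Distances between native and introduced ranges are computed as
great-circle (haversine) distances between region centroids on a sphere
of mean earth radius 6371.0088 km; the sub-half-percent error of the
spherical model is irrelevant next to the log transform applied
downstream.  Centroids are spherical: the normalized 3-D mean of the
unit vectors of the input points, which behaves sensibly for
archipelagos and ranges that straddle the antimeridian.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088

__all__ = ["EARTH_RADIUS_KM", "centroid", "great_circle_km", "log_distance",
           "UndefinedCentroidError"]


class UndefinedCentroidError(ValueError):
    """The unit-vector mean has (near-)zero norm, e.g. antipodal points."""


def _check_latlon(lat: np.ndarray, lon: np.ndarray) -> None:
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    if np.any((lon <= -180) | (lon > 180)):
        raise ValueError("longitude outside (-180, 180]")


def centroid(lats, lons) -> tuple[float, float]:
    """Spherical centroid (lat, lon) of a set of points, in degrees.

    Raises UndefinedCentroidError when the mean unit vector has norm
    below 1e-9 (points balanced around the sphere, e.g. two antipodes).
    """
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    if lats.size == 0:
        raise ValueError("centroid of zero points")
    _check_latlon(lats, lons)
    phi, lam = np.radians(lats), np.radians(lons)
    x = np.cos(phi) * np.cos(lam)
    y = np.cos(phi) * np.sin(lam)
    z = np.sin(phi)
    v = np.array([x.mean(), y.mean(), z.mean()])
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise UndefinedCentroidError("unit-vector mean has near-zero norm")
    v /= norm
    lat = np.degrees(np.arcsin(np.clip(v[2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(v[1], v[0]))
    if lon <= -180.0:
        lon += 360.0
    return float(lat), float(lon)


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between (lat, lon) points in degrees."""
    lat1, lon1 = a
    lat2, lon2 = b
    _check_latlon(np.array([lat1, lat2]), np.array([lon1, lon2]))
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def log_distance(d_km: float) -> float:
    """log(d + 1): the +1 offset keeps within-jurisdiction introductions
    (centroid distance 0) finite.  Standardization happens downstream."""
    d = np.asarray(d_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = np.log1p(d)
    return float(out) if out.ndim == 0 else out
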