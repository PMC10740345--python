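"""Spherical geometry primitives.

All distance work in this package is done on a sphere of mean radius
6371.0088 km.  The thresholds that drive the analysis (5 km/h stationarity,
25 km site radius, 50 km merge/revisit distance) are tens of kilometres, so
the < 0.5 % difference from an ellipsoid is immaterial; the spherical model
is also safe for dateline-crossing tracks (East Russian Arctic breeding
grounds), which projected planar work is not.

Functions accept scalars or numpy arrays of decimal degrees (WGS84) and
broadcast in the numpy way.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import shapely
from shapely.geometry import Point as _ShpPoint
from shapely.geometry import Polygon as _ShpPolygon

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "normalize_lon",
    "gc_distance_km",
    "pairwise_gc_distance_km",
    "ground_speed_kmh",
    "spherical_centroid",
    "initial_bearing_deg",
    "destination_point",
    "to_local_plane",
    "from_local_plane",
    "point_in_region",
]


class GeoPoint(NamedTuple):
    """A location in decimal degrees (WGS84)."""

    lat: float
    lon: float


def normalize_lon(lon):
    """Map longitudes into (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    out = -((-lon + 180.0) % 360.0 - 180.0)
    return out if out.ndim else float(out)


def gc_distance_km(lat1, lon1, lat2, lon2):
    """Great-circle (haversine) distance in km; symmetric and non-negative."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def pairwise_gc_distance_km(lats, lons):
    """Full n x n great-circle distance matrix."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    return gc_distance_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])


def ground_speed_kmh(lat1, lon1, t1, lat2, lon2, t2) -> float:
    """Great-circle displacement divided by elapsed time, km/h.

    ``t1``/``t2`` are timestamps supporting subtraction to a timedelta.
    Raises ``ValueError`` for zero or negative elapsed time.
    """
    dt_h = (t2 - t1).total_seconds() / 3600.0
    if dt_h <= 0:
        raise ValueError(f"non-positive elapsed time between fixes: {dt_h} h")
    return float(gc_distance_km(lat1, lon1, lat2, lon2)) / dt_h


def _to_unit_vectors(lats, lons):
    lat = np.radians(np.asarray(lats, dtype=float))
    lon = np.radians(np.asarray(lons, dtype=float))
    return np.stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1
    )


def spherical_centroid(lats, lons, weights=None) -> GeoPoint:
    """Normalized mean of unit vectors on the sphere.

    Raises ``ValueError`` on an empty set or when the resultant vector
    vanishes (antipodal degenerate configuration).
    """
    v = _to_unit_vectors(lats, lons)
    if v.size == 0:
        raise ValueError("spherical_centroid of empty point set")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        v = v * w[:, None]
    m = v.reshape(-1, 3).sum(axis=0)
    norm = np.linalg.norm(m)
    if norm < 1e-12:
        raise ValueError("degenerate (antipodal) point set: zero resultant vector")
    m /= norm
    lat = np.degrees(np.arcsin(np.clip(m[2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(m[1], m[0]))
    return GeoPoint(float(lat), normalize_lon(float(lon)))


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, degrees clockwise from north."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    b = np.degrees(np.arctan2(y, x)) % 360.0
    return b if b.ndim else float(b)


def destination_point(lat, lon, bearing_deg, distance_km):
    """Point reached travelling ``distance_km`` along ``bearing_deg`` on a great circle."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(brg))
    lon2 = lon1 + np.arctan2(
        np.sin(brg) * np.sin(delta) * np.cos(lat1),
        np.cos(delta) - np.sin(lat1) * np.sin(lat2),
    )
    lat2 = np.degrees(lat2)
    lon2 = normalize_lon(np.degrees(lon2))
    if np.ndim(lat2) == 0:
        return GeoPoint(float(lat2), float(lon2))
    return lat2, lon2


def gc_interpolate(lat1, lon1, lat2, lon2, frac):
    """Points along the great circle from 1 to 2 at fraction(s) ``frac`` in [0, 1]."""
    v1 = _to_unit_vectors(lat1, lon1)
    v2 = _to_unit_vectors(lat2, lon2)
    omega = np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))
    frac = np.asarray(frac, dtype=float)
    if omega < 1e-12:
        v = np.broadcast_to(v1, frac.shape + (3,)).copy()
    else:
        s = np.sin(omega)
        v = (np.sin((1.0 - frac)[..., None] * omega) * v1
             + np.sin(frac[..., None] * omega) * v2) / s
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
    lat = np.degrees(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    lon = normalize_lon(np.degrees(np.arctan2(v[..., 1], v[..., 0])))
    return lat, lon


# --- local azimuthal-equidistant plane -------------------------------------
#
# The state-space smoother works in a plane centred on the track.  An
# azimuthal-equidistant projection preserves distance and bearing from the
# centre, which is exactly what a local Kalman model needs at the scale of a
# staging region.

def to_local_plane(lats, lons, lat0: float, lon0: float):
    """Project to (x_east, y_north) km in an azimuthal-equidistant plane at (lat0, lon0)."""
    d = gc_distance_km(lat0, lon0, lats, lons)
    b = np.radians(initial_bearing_deg(lat0, lon0, lats, lons))
    return d * np.sin(b), d * np.cos(b)


def from_local_plane(x, y, lat0: float, lon0: float):
    """Inverse of :func:`to_local_plane`.

    Returns a :class:`GeoPoint` for scalar input, ``(lats, lons)`` arrays otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.hypot(x, y)
    b = np.degrees(np.arctan2(x, y))
    return destination_point(lat0, lon0, b, d)


def region_polygon(vertices) -> _ShpPolygon:
    """Build a shapely polygon from (lon, lat) vertices; must be simple."""
    poly = _ShpPolygon(vertices)
    if not poly.is_valid:
        raise ValueError("region polygon is not simple (self-intersecting or degenerate)")
    return poly


def point_in_region(lat: float, lon: float, polygon: _ShpPolygon) -> bool:
    """Even-odd point-in-polygon test; boundary points count as inside."""
    return bool(polygon.covers(_ShpPoint(lon, lat)))


def points_in_region(lats, lons, polygon: _ShpPolygon) -> np.ndarray:
    """Vectorized membership test (boundary inclusive)."""
    pts = shapely.points(np.asarray(lons, dtype=float), np.asarray(lats, dtype=float))
    return shapely.covers(polygon, pts)
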