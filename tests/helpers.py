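"""Shared builders for synthetic fixes and tracks used across the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from shorefid import Fix, Track
from shorefid.geo import destination_point

T0 = pd.Timestamp("2016-01-05 00:00", tz="UTC")


def fix(ind="b1", hours=0.0, lat=0.0, lon=0.0, lc="3", **kw) -> Fix:
    return Fix(ind, T0 + pd.Timedelta(hours=hours), lat, lon, lc, **kw)


def track(points, ind="b1", species="GK") -> Track:
    """Build a track from (hours, lat, lon) or (hours, lat, lon, loc_class) tuples."""
    fixes = []
    for p in points:
        h, lat, lon = p[0], p[1], p[2]
        lc = p[3] if len(p) > 3 else "3"
        fixes.append(fix(ind, h, lat, lon, lc))
    return Track(individual_id=ind, species=species, fixes=fixes)


def cluster_points(center_lat, center_lon, n, spread_km, rng) -> tuple[np.ndarray, np.ndarray]:
    """n points isotropically scattered around a centre with the given sd (km)."""
    lats, lons = [], []
    for _ in range(n):
        e, s = rng.normal(0.0, spread_km, 2)
        p = destination_point(center_lat, center_lon,
                              float(np.degrees(np.arctan2(e, s))), float(np.hypot(e, s)))
        lats.append(p.lat)
        lons.append(p.lon)
    return np.array(lats), np.array(lons)


def stationary_track(sites, fixes_per_site=30, spread_km=1.0, interval_h=1.5,
                     gap_h=48.0, ind="b1", species="GK", loc_class="1", seed=0,
                     start_h=0.0) -> Track:
    """A track dwelling at each (lat, lon) site in turn, with isotropic noise.

    Consecutive sites are separated by a fast transit so that only the
    dwelling fixes are stationary.
    """
    rng = np.random.default_rng(seed)
    fixes = []
    h = start_h
    for lat, lon in sites:
        lats, lons = cluster_points(lat, lon, fixes_per_site, spread_km, rng)
        for la, lo in zip(lats, lons):
            fixes.append(fix(ind, h, float(la), float(lo), loc_class))
            h += interval_h
        h += gap_h
    return Track(individual_id=ind, species=species, fixes=fixes)
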