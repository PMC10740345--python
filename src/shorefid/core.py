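"""Domain types and pipeline configuration.

The analysis revolves around a handful of record types: an Argos ``Fix``,
a per-individual ``Track``, a mark-resighting ``ResightingRecord``, a named
``Region`` polygon, and the 2x2 ``Contingency2x2`` tables that feed the
exact tests.  ``PipelineConfig`` houses every numeric constant used by the
pipeline, with defaults matching the study design (120 km/h speed filter,
10 km redundant distance, 5 km/h stationarity, 25 km site radius, 50 km
merge/revisit distance, 8 h on / 25 h off duty cycle, species-specific first
departure dates), all overridable from a YAML file.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd
import yaml
from shapely.geometry import Polygon

from .geo import normalize_lon, region_polygon

logger = logging.getLogger("shorefid")

#: Argos location classes in decreasing quality order.
LOC_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")
STANDARD_CLASSES = frozenset({"3", "2", "1"})
AUXILIARY_CLASSES = frozenset({"0", "A", "B", "Z"})
_CLASS_RANK = {c: i for i, c in enumerate(LOC_CLASSES)}


def class_rank(loc_class: str) -> int:
    """Quality rank of a location class: 0 is best (class 3), 6 is worst (Z)."""
    return _CLASS_RANK[loc_class]


@dataclass(frozen=True)
class Fix:
    """One Argos telemetry location.

    Error-ellipse fields (1-sigma semi-axes in metres, orientation in degrees
    clockwise from north) are present only for Kalman-processed locations.
    """

    individual_id: str
    timestamp: pd.Timestamp
    lat: float
    lon: float
    loc_class: str
    ellipse_semi_major_m: Optional[float] = None
    ellipse_semi_minor_m: Optional[float] = None
    ellipse_orientation_deg: Optional[float] = None

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        object.__setattr__(self, "lon", float(normalize_lon(self.lon)))
        if self.loc_class not in _CLASS_RANK:
            raise ValueError(f"unknown Argos location class: {self.loc_class!r}")
        smaj, smin = self.ellipse_semi_major_m, self.ellipse_semi_minor_m
        if (smaj is None) != (smin is None):
            raise ValueError("error ellipse requires both semi-axes")
        if smaj is not None:
            if smin < 0 or smaj < smin:
                raise ValueError(
                    f"ellipse axes must satisfy semi_major >= semi_minor >= 0, "
                    f"got {smaj}/{smin}"
                )

    @property
    def is_standard(self) -> bool:
        return self.loc_class in STANDARD_CLASSES


@dataclass
class Track:
    """Time-ordered fixes for one individual."""

    individual_id: str
    species: str
    fixes: list[Fix]
    release_time: Optional[pd.Timestamp] = None

    def __post_init__(self):
        for f in self.fixes:
            if f.individual_id != self.individual_id:
                raise ValueError(
                    f"fix individual {f.individual_id!r} != track {self.individual_id!r}"
                )
        times = [f.timestamp for f in self.fixes]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("track fixes must be strictly increasing in time")
        if self.release_time is None and self.fixes:
            self.release_time = self.fixes[0].timestamp

    def __len__(self) -> int:
        return len(self.fixes)

    def lats(self):
        return [f.lat for f in self.fixes]

    def lons(self):
        return [f.lon for f in self.fixes]

    def times(self):
        return [f.timestamp for f in self.fixes]


@dataclass(frozen=True)
class ResightingRecord:
    """One observation of a marked individual at a named site on a date."""

    individual_id: str
    species: str
    date: dt.date
    site_id: str
    site_lat: float
    site_lon: float


@dataclass
class Region:
    """A named region given as a closed (lon, lat) ring; must be simple."""

    name: str
    polygon: Polygon

    @classmethod
    def from_vertices(cls, name: str, lonlat_vertices: Sequence[tuple[float, float]]) -> "Region":
        return cls(name, region_polygon(lonlat_vertices))

    @classmethod
    def from_bbox(cls, name: str, lon_min, lat_min, lon_max, lat_max) -> "Region":
        ring = [(lon_min, lat_min), (lon_max, lat_min), (lon_max, lat_max), (lon_min, lat_max)]
        return cls(name, region_polygon(ring))


@dataclass(frozen=True)
class Contingency2x2:
    """2x2 integer table; rows are species, columns an outcome dichotomy."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError(f"table entries must be non-negative integers, got {v}")
        if self.total == 0:
            raise ValueError("contingency table must have a positive total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self):
        return [[self.a, self.b], [self.c, self.d]]


# --- configuration ----------------------------------------------------------

def _default_regions() -> dict[str, Region]:
    # Bounding boxes generous enough to contain the study areas: the Yellow
    # Sea staging coast and the Northwest Australia non-breeding coast.
    return {
        "yellow_sea": Region.from_bbox("yellow_sea", 116.0, 30.0, 127.5, 41.5),
        "northwest_australia": Region.from_bbox("northwest_australia", 112.0, -23.0, 138.0, -9.0),
    }


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, with study-design defaults."""

    # Argos filtering
    vmax_kmh: float = 120.0           # maximum sustainable rate of movement
    maxredun_km: float = 10.0         # maximum redundant distance
    # stop detection / clustering
    stationary_speed_kmh: float = 5.0
    site_radius_km: float = 25.0
    containment_frac: float = 0.95
    merge_km: float = 50.0
    revisit_km: float = 50.0
    min_site_locs: int = 3
    min_site_span_h: float = 2.0
    max_clusters: int = 15
    # duty cycle
    duty_on_h: float = 8.0
    duty_off_h: float = 25.0
    # annual-cycle calendar (month, day) boundaries
    first_departure: dict = field(default_factory=lambda: {"GK": (3, 22), "BTG": (4, 4)})
    departure_buffer_days: int = 7
    nonbreeding_resight_start: tuple = (11, 1)
    northward_window: tuple = ((3, 1), (6, 30))
    southward_window: tuple = ((7, 1), (11, 30))
    # tracking-fidelity extras
    return_latitude_deg: float = -10.0   # "back in the non-breeding range" latitude
    residency_days: float = 7.0          # minimum stay to call a post-migration site
    # resighting analysis
    min_sightings: int = 2
    resight_grid_deg: float = 0.25       # site id synthesized from coords on this grid
    # smoothing
    smooth_sigma_bounds: tuple = (0.01, 100.0)   # km / sqrt(h)
    class_r68_km: dict = field(default_factory=lambda: {
        "3": 0.25, "2": 0.5, "1": 1.5, "0": 5.0, "A": 8.0, "B": 15.0, "Z": 15.0,
    })
    # regions
    regions: dict = field(default_factory=_default_regions)
    rng_seed: int = 0

    def __post_init__(self):
        positive = {
            "vmax_kmh": self.vmax_kmh, "maxredun_km": self.maxredun_km,
            "stationary_speed_kmh": self.stationary_speed_kmh,
            "site_radius_km": self.site_radius_km, "merge_km": self.merge_km,
            "revisit_km": self.revisit_km, "min_site_locs": self.min_site_locs,
            "min_site_span_h": self.min_site_span_h,
            "duty_on_h": self.duty_on_h, "duty_off_h": self.duty_off_h,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not 0.0 < self.containment_frac <= 1.0:
            raise ValueError(f"containment_frac must be in (0, 1], got {self.containment_frac}")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    # -- (de)serialization ---------------------------------------------------
    _SIMPLE_KEYS = (
        "vmax_kmh", "maxredun_km", "stationary_speed_kmh", "site_radius_km",
        "containment_frac", "merge_km", "revisit_km", "min_site_locs",
        "min_site_span_h", "max_clusters", "duty_on_h", "duty_off_h",
        "departure_buffer_days", "return_latitude_deg", "residency_days",
        "min_sightings", "resight_grid_deg", "rng_seed",
    )

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self._SIMPLE_KEYS}
        data["first_departure"] = {sp: list(md) for sp, md in self.first_departure.items()}
        data["nonbreeding_resight_start"] = list(self.nonbreeding_resight_start)
        data["northward_window"] = [list(t) for t in self.northward_window]
        data["southward_window"] = [list(t) for t in self.southward_window]
        data["smooth_sigma_bounds"] = list(self.smooth_sigma_bounds)
        data["class_r68_km"] = dict(self.class_r68_km)
        data["regions"] = {
            name: [list(xy) for xy in r.polygon.exterior.coords[:-1]]
            for name, r in self.regions.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {k: data[k] for k in cls._SIMPLE_KEYS if k in data}
        if "first_departure" in data:
            kwargs["first_departure"] = {
                sp: tuple(md) for sp, md in data["first_departure"].items()
            }
        if "nonbreeding_resight_start" in data:
            kwargs["nonbreeding_resight_start"] = tuple(data["nonbreeding_resight_start"])
        for key in ("northward_window", "southward_window"):
            if key in data:
                kwargs[key] = tuple(tuple(t) for t in data[key])
        if "smooth_sigma_bounds" in data:
            kwargs["smooth_sigma_bounds"] = tuple(data["smooth_sigma_bounds"])
        if "class_r68_km" in data:
            kwargs["class_r68_km"] = {str(k): float(v) for k, v in data["class_r68_km"].items()}
        if "regions" in data:
            kwargs["regions"] = {
                name: Region.from_vertices(name, [tuple(xy) for xy in ring])
                for name, ring in data["regions"].items()
            }
        return cls(**kwargs)


def month_day_in_window(date: dt.date, window) -> bool:
    """Whether a date's (month, day) falls inside a calendar window.

    The window is ((m1, d1), (m2, d2)); windows wrapping the year boundary
    (e.g. 1 Nov - 15 Mar) are supported.
    """
    (m1, d1), (m2, d2) = window
    md = (date.month, date.day)
    lo, hi = (m1, d1), (m2, d2)
    if lo <= hi:
        return lo <= md <= hi
    return md >= lo or md <= hi
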