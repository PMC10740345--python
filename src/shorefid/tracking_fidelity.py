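"""Tracking-based site-fidelity metrics.

Non-breeding analysis: each individual is windowed from release to one week
before the first departure date of a tracked conspecific (22 March for Great
Knots, 4 April for Bar-tailed Godwits), the stop-site machinery is run on
the windowed track, and the individual is classed as having *moved* if it
used two or more sites (sites are >= 50 km apart by construction) or used a
site more than 50 km from its release site.

Migration analysis: from each individual's first tracked migration, a
southward Yellow Sea site is a *revisit* if its centroid lies within 50 km
of one of the same bird's northward site centroids; the degree of fidelity
is the proportion of southward staging time (extrapolated arrival to
departure) spent at revisited sites.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import Contingency2x2, PipelineConfig, Region, Track, logger
from .geo import GeoPoint, gc_distance_km
from .stopover import StopSite, find_sites

__all__ = [
    "NonbreedingUsage", "SeasonalFidelity", "nonbreeding_window",
    "nonbreeding_usage", "returned_after_migration", "seasonal_revisit",
    "species_summary",
]


@dataclass(frozen=True)
class NonbreedingUsage:
    """Site usage of one individual during its non-breeding window."""

    individual_id: str
    species: str
    n_sites_used: int
    moved: bool
    window_start: pd.Timestamp
    window_end: pd.Timestamp


@dataclass(frozen=True)
class SeasonalFidelity:
    """Seasonal (northward vs southward) site fidelity of one individual."""

    individual_id: str
    species: str
    revisited: bool
    prop_time_revisited: float
    n_sites_north: int
    n_sites_south: int


class EmptyWindowError(ValueError):
    """The release falls after the end of the non-breeding window."""


def nonbreeding_window(species: str, release_time: pd.Timestamp,
                       cfg: PipelineConfig | None = None) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Window from release to a week before the species' first departure date.

    The departure date is taken in the first year it occurs after release.
    """
    cfg = cfg or PipelineConfig()
    if species not in cfg.first_departure:
        raise ValueError(f"no first-departure date configured for species {species!r}")
    month, day = cfg.first_departure[species]
    dep = pd.Timestamp(dt.datetime(release_time.year, month, day), tz=release_time.tz)
    if dep <= release_time:
        dep = pd.Timestamp(dt.datetime(release_time.year + 1, month, day), tz=release_time.tz)
    end = dep - pd.Timedelta(days=cfg.departure_buffer_days)
    if end <= release_time:
        raise EmptyWindowError(
            f"release {release_time} is after the non-breeding window end {end}")
    return release_time, end


def _window_track(track: Track, start, end) -> Track:
    fixes = [f for f in track.fixes if start <= f.timestamp <= end]
    return Track(individual_id=track.individual_id, species=track.species,
                 fixes=fixes, release_time=track.release_time)


def nonbreeding_usage(
    track: Track,
    cfg: PipelineConfig | None = None,
    region: Optional[Region] = None,
    origin: Optional[GeoPoint] = None,
) -> Optional[NonbreedingUsage]:
    """Count distinct non-breeding sites and flag movers.

    Returns ``None`` (logged) when the window contains no fixes or no site
    survives the size/span filters; such individuals are excluded from
    summaries rather than counted either way.
    """
    cfg = cfg or PipelineConfig()
    start, end = nonbreeding_window(track.species, track.release_time, cfg)
    win = _window_track(track, start, end)
    if not win.fixes:
        logger.warning("no fixes in the non-breeding window for %s", track.individual_id)
        return None
    sites = find_sites(win, region, cfg, season="nonbreeding")
    if not sites:
        logger.warning("no non-breeding site detected for %s", track.individual_id)
        return None
    if origin is None:
        origin = sites[0].centroid
    far = any(
        float(gc_distance_km(s.centroid.lat, s.centroid.lon, origin.lat, origin.lon))
        > cfg.merge_km
        for s in sites
    )
    n = len(sites)
    return NonbreedingUsage(
        individual_id=track.individual_id, species=track.species,
        n_sites_used=n, moved=(n >= 2) or far,
        window_start=start, window_end=end,
    )


def returned_after_migration(
    track: Track,
    origin_centroid: GeoPoint,
    cfg: PipelineConfig | None = None,
) -> Optional[bool]:
    """Whether the first post-migration residency site is within 50 km of origin.

    The post-migration portion starts at the northernmost fix; a residency
    site is the first stop site of at least ``residency_days`` south of the
    configured return latitude.  ``None`` means the round trip cannot be
    assessed (tag stopped before a residency was established).
    """
    cfg = cfg or PipelineConfig()
    if not track.fixes:
        return None
    lats = np.array([f.lat for f in track.fixes])
    peak = int(np.argmax(lats))
    post = track.fixes[peak:]
    south = [f for f in post if f.lat <= cfg.return_latitude_deg]
    if not south:
        logger.warning("no post-migration fixes below %.1f deg for %s",
                       cfg.return_latitude_deg, track.individual_id)
        return None
    sub = Track(individual_id=track.individual_id, species=track.species,
                fixes=south, release_time=track.release_time)
    sites = find_sites(sub, None, cfg, season="nonbreeding")
    residency = [s for s in sites if s.stay_duration_h >= cfg.residency_days * 24.0]
    if not residency:
        logger.warning("no post-migration residency of >= %.0f days for %s",
                       cfg.residency_days, track.individual_id)
        return None
    first = min(residency, key=lambda s: s.arrival_time)
    d = float(gc_distance_km(first.centroid.lat, first.centroid.lon,
                             origin_centroid.lat, origin_centroid.lon))
    return d <= cfg.merge_km


def seasonal_revisit(
    itinerary_north: list[StopSite],
    itinerary_south: list[StopSite],
    cfg: PipelineConfig | None = None,
    species: str = "UNK",
) -> Optional[SeasonalFidelity]:
    """Seasonal fidelity from one individual's first tracked migration.

    A southward site matches when its centroid is within ``revisit_km``
    (50 km) of any northward site centroid.  The proportion of time at
    revisited sites uses extrapolated arrival-to-departure stay durations
    over the total southward staging duration.  An empty southward itinerary
    returns ``None`` (excluded from summaries).
    """
    cfg = cfg or PipelineConfig()
    if not itinerary_south:
        return None
    individual = itinerary_south[0].individual_id
    matched_time = 0.0
    total_time = 0.0
    any_match = False
    for s in itinerary_south:
        dur = max(0.0, s.stay_duration_h)
        total_time += dur
        match = any(
            float(gc_distance_km(s.centroid.lat, s.centroid.lon,
                                 n.centroid.lat, n.centroid.lon)) <= cfg.revisit_km
            for n in itinerary_north
        )
        if match:
            any_match = True
            matched_time += dur
    prop = matched_time / total_time if total_time > 0 else 0.0
    return SeasonalFidelity(
        individual_id=individual, species=species,
        revisited=any_match, prop_time_revisited=prop,
        n_sites_north=len(itinerary_north), n_sites_south=len(itinerary_south),
    )


def _median_range(values) -> dict:
    if not values:
        return {"median": float("nan"), "min": None, "max": None}
    return {"median": float(np.median(values)), "min": int(min(values)), "max": int(max(values))}


def species_summary(
    usages: list[NonbreedingUsage],
    fidelities: list[SeasonalFidelity],
    species_pair: tuple[str, str] = ("BTG", "GK"),
) -> dict:
    """Cohort summary: percentages, site-count medians, and 2x2 tables.

    Row order of every table follows ``species_pair``; columns are
    (faithful outcome, unfaithful outcome).  Tables are only built when both
    species contribute at least one individual.
    """
    sp1, sp2 = species_pair
    out: dict = {"species_pair": species_pair, "nonbreeding": {}, "seasonal": {}}

    by_sp_usage = {sp: [u for u in usages if u.species == sp] for sp in species_pair}
    for sp, us in by_sp_usage.items():
        n = len(us)
        movers = sum(u.moved for u in us)
        out["nonbreeding"][sp] = {
            "n": n, "movers": movers,
            "pct_single_site": 100.0 * (n - movers) / n if n else float("nan"),
        }
    if all(len(v) for v in by_sp_usage.values()):
        u1, u2 = by_sp_usage[sp1], by_sp_usage[sp2]
        out["nonbreeding"]["table"] = Contingency2x2(
            a=sum(not u.moved for u in u1), b=sum(u.moved for u in u1),
            c=sum(not u.moved for u in u2), d=sum(u.moved for u in u2),
        )

    by_sp_fid = {sp: [f for f in fidelities if f.species == sp] for sp in species_pair}
    for sp, fs in by_sp_fid.items():
        n = len(fs)
        rev = sum(f.revisited for f in fs)
        out["seasonal"][sp] = {
            "n": n, "revisited": rev,
            "pct_revisited": 100.0 * rev / n if n else float("nan"),
            "median_prop_time": float(np.median([f.prop_time_revisited for f in fs]))
            if n else float("nan"),
            "n_sites_north": _median_range([f.n_sites_north for f in fs]),
            "n_sites_south": _median_range([f.n_sites_south for f in fs]),
        }
    if all(len(v) for v in by_sp_fid.values()):
        f1, f2 = by_sp_fid[sp1], by_sp_fid[sp2]
        out["seasonal"]["table"] = Contingency2x2(
            a=sum(f.revisited for f in f1), b=sum(not f.revisited for f in f1),
            c=sum(f.revisited for f in f2), d=sum(not f.revisited for f in f2),
        )
        out["seasonal"]["prop_time"] = {
            "y": [f.prop_time_revisited for f in f1] + [f.prop_time_revisited for f in f2],
            "group": [0] * len(f1) + [1] * len(f2),
        }
    return out
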