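"""Stopover-site identification from stationary locations.

The core procedure, run per individual and per migration season:

1. *Stationary detection* -- fixes inside the target region whose ground
   speed (the larger of the two adjacent retained-segment speeds; terminal
   fixes use their single segment) is strictly below 5 km/h.
2. *Clustering* -- complete-linkage agglomerative clustering on the
   great-circle distance matrix; the number of clusters is chosen by the
   mean silhouette width over k = 2..min(n-1, 15) (ties to the smallest k).
   If all points already lie within the 25 km site radius of their common
   centroid (at the 95% containment level), a single cluster is returned
   without consulting the silhouette, since the silhouette is undefined at
   k = 1.
3. *Containment* -- while any cluster has more than 5% of members beyond
   25 km of its centroid, clustering is repeated with k incremented by one
   (capped at n - 1; the cap labeling is returned with a warning).  This
   makes monotone, deterministic progress toward compact sites.
4. *Merging* -- site centroids closer than 50 km are merged, closest pair
   first, with member-weighted spherical centroids, until all pairwise
   centroid distances are >= 50 km.
5. *Filtering* -- sites with fewer than 3 stationary locations, or whose
   first and last locations are less than 2 h apart, are discarded.
6. *Timing* -- arrival and departure are extrapolated to the crossing of
   the 25 km site radius assuming constant speed along the segment joining
   the site's terminal member fix and the adjacent track fix.

Everything here is deterministic given the input and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import complete, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .core import PipelineConfig, Region, Track, logger, month_day_in_window
from .geo import GeoPoint, gc_distance_km, pairwise_gc_distance_km, points_in_region, spherical_centroid
from .smoother import SmoothedTrack

__all__ = [
    "StationaryLoc", "StopSite", "detect_stationary", "cluster_stationary",
    "enforce_containment", "merge_close_sites", "filter_sites",
    "estimate_times", "find_sites", "build_itinerary",
]


@dataclass(frozen=True)
class StationaryLoc:
    """A below-threshold-speed location inside the target region."""

    individual_id: str
    time: pd.Timestamp
    lat: float
    lon: float
    speed_kmh: float
    track_index: int     # position within the (filtered) track


@dataclass
class StopSite:
    """A cluster of stationary locations used as a stopover/residency site."""

    site_id: str
    individual_id: str
    season: str                      # "northward", "southward" or "nonbreeding"
    centroid: GeoPoint
    members: list[StationaryLoc]
    first_time: pd.Timestamp = field(init=False)
    last_time: pd.Timestamp = field(init=False)
    arrival_time: Optional[pd.Timestamp] = None
    departure_time: Optional[pd.Timestamp] = None

    def __post_init__(self):
        if not self.members:
            raise ValueError("a stop site needs at least one member location")
        times = [m.time for m in self.members]
        self.first_time = min(times)
        self.last_time = max(times)
        if self.arrival_time is None:
            self.arrival_time = self.first_time
        if self.departure_time is None:
            self.departure_time = self.last_time

    @property
    def span_h(self) -> float:
        return (self.last_time - self.first_time).total_seconds() / 3600.0

    @property
    def stay_duration_h(self) -> float:
        return (self.departure_time - self.arrival_time).total_seconds() / 3600.0


def _track_arrays(track: Track, smoothed: Optional[SmoothedTrack] = None):
    """Times/positions used for analysis: fitted locations when available."""
    times = [f.timestamp for f in track.fixes]
    if smoothed is not None and smoothed.smoothed:
        if len(smoothed.fitted_lat) != len(track.fixes):
            raise ValueError("smoothed track does not match the track's fixes")
        return times, np.asarray(smoothed.fitted_lat), np.asarray(smoothed.fitted_lon)
    return times, np.array([f.lat for f in track.fixes]), np.array([f.lon for f in track.fixes])


def segment_speeds_kmh(times, lats, lons) -> np.ndarray:
    """Per-fix ground speed: the larger of the two adjacent segment speeds.

    A fix belonging to a genuine stay has slow segments on both sides (duty-
    cycle gaps included), whereas a large position error produces at least
    one fast implied segment, so taking the maximum of the adjacent segment
    speeds classifies stays correctly while rejecting error outliers that a
    one-sided definition lets through after a long transmission gap.  The
    first and last fixes have only one adjacent segment and use it.
    """
    n = len(times)
    if n == 1:
        return np.zeros(1)
    d = gc_distance_km(lats[:-1], lons[:-1], lats[1:], lons[1:])
    dt_h = np.array([(times[i + 1] - times[i]).total_seconds() / 3600.0 for i in range(n - 1)])
    seg = np.asarray(d) / dt_h
    speeds = np.empty(n)
    speeds[0] = seg[0]
    speeds[-1] = seg[-1]
    if n > 2:
        speeds[1:-1] = np.maximum(seg[:-1], seg[1:])
    return speeds


def detect_stationary(
    track: Track,
    region: Optional[Region],
    cfg: PipelineConfig | None = None,
    smoothed: Optional[SmoothedTrack] = None,
) -> list[StationaryLoc]:
    """Fixes inside ``region`` with ground speed strictly below the threshold.

    ``region=None`` disables the spatial gate (used for the non-breeding
    analysis where the window, not a polygon, bounds the data).
    """
    cfg = cfg or PipelineConfig()
    if not track.fixes:
        return []
    times, lats, lons = _track_arrays(track, smoothed)
    speeds = segment_speeds_kmh(times, lats, lons)
    if region is not None:
        inside = points_in_region(lats, lons, region.polygon)
    else:
        inside = np.ones(len(lats), dtype=bool)
    out = []
    for i in range(len(lats)):
        if inside[i] and speeds[i] < cfg.stationary_speed_kmh:
            out.append(StationaryLoc(
                individual_id=track.individual_id, time=times[i],
                lat=float(lats[i]), lon=float(lons[i]),
                speed_kmh=float(speeds[i]), track_index=i,
            ))
    return out


# --- clustering -------------------------------------------------------------

def _containment_ok(lats, lons, labels, cfg) -> bool:
    for lab in np.unique(labels):
        sel = labels == lab
        c = spherical_centroid(lats[sel], lons[sel])
        d = gc_distance_km(lats[sel], lons[sel], c.lat, c.lon)
        if np.mean(np.asarray(d) <= cfg.site_radius_km) < cfg.containment_frac:
            return False
    return True


def _cut_tree(linkage, k: int) -> np.ndarray:
    return fcluster(linkage, t=k, criterion="maxclust") - 1


def cluster_stationary(locs, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Complete-linkage clustering with silhouette model selection.

    Returns integer labels (0-based).  Raises ``ValueError`` on empty input.
    """
    cfg = cfg or PipelineConfig()
    lats = np.array([l.lat for l in locs])
    lons = np.array([l.lon for l in locs])
    n = len(lats)
    if n == 0:
        raise ValueError("cannot cluster zero stationary locations")
    if n == 1:
        return np.zeros(1, dtype=int)
    # one-cluster shortcut: compact at the site radius already
    if _containment_ok(lats, lons, np.zeros(n, dtype=int), cfg):
        return np.zeros(n, dtype=int)
    dmat = pairwise_gc_distance_km(lats, lons)
    np.fill_diagonal(dmat, 0.0)
    if n == 2:
        return np.arange(2)
    linkage = complete(squareform(dmat, checks=False))
    best_k, best_score = None, -np.inf
    for k in range(2, min(n - 1, cfg.max_clusters) + 1):
        labels = _cut_tree(linkage, k)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(dmat, labels, metric="precomputed")
        if score > best_score + 1e-12:   # strict improvement; ties keep smaller k
            best_k, best_score = k, score
    if best_k is None:
        return _cut_tree(linkage, 2)
    return _cut_tree(linkage, best_k)


def enforce_containment(locs, labels: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Re-cluster with k+1 until every cluster meets the 95%-within-25-km rule."""
    cfg = cfg or PipelineConfig()
    lats = np.array([l.lat for l in locs])
    lons = np.array([l.lon for l in locs])
    n = len(lats)
    if _containment_ok(lats, lons, labels, cfg):
        return labels
    dmat = pairwise_gc_distance_km(lats, lons)
    np.fill_diagonal(dmat, 0.0)
    linkage = complete(squareform(dmat, checks=False))
    k = len(np.unique(labels)) + 1
    labels_k = labels
    while k <= max(n - 1, 2):
        labels_k = _cut_tree(linkage, k)
        if _containment_ok(lats, lons, labels_k, cfg):
            return labels_k
        k += 1
    logger.warning("containment not reachable at k = n - 1; returning max-k labeling")
    return labels_k


# --- sites ------------------------------------------------------------------

def _make_site(individual_id: str, season: str, members) -> StopSite:
    c = spherical_centroid([m.lat for m in members], [m.lon for m in members])
    return StopSite(
        site_id="", individual_id=individual_id, season=season,
        centroid=c, members=sorted(members, key=lambda m: m.time),
    )


def merge_close_sites(sites: list[StopSite], cfg: PipelineConfig | None = None) -> list[StopSite]:
    """Merge the closest centroid pair under 50 km, repeatedly."""
    cfg = cfg or PipelineConfig()
    sites = list(sites)
    while len(sites) > 1:
        best = None
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                d = gc_distance_km(sites[i].centroid.lat, sites[i].centroid.lon,
                                   sites[j].centroid.lat, sites[j].centroid.lon)
                if d < cfg.merge_km and (best is None or d < best[0]):
                    best = (d, i, j)
        if best is None:
            break
        _, i, j = best
        merged = _make_site(sites[i].individual_id, sites[i].season,
                            sites[i].members + sites[j].members)
        sites = [s for idx, s in enumerate(sites) if idx not in (i, j)] + [merged]
    return sites


def filter_sites(sites: list[StopSite], cfg: PipelineConfig | None = None) -> list[StopSite]:
    """Keep sites with >= 3 member locations spanning >= 2 h."""
    cfg = cfg or PipelineConfig()
    return [s for s in sites
            if len(s.members) >= cfg.min_site_locs and s.span_h >= cfg.min_site_span_h]


def estimate_times(site: StopSite, track: Track, cfg: PipelineConfig | None = None,
                   smoothed: Optional[SmoothedTrack] = None) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Extrapolate arrival/departure to the crossing of the site radius.

    Departure: constant speed is assumed between the last member fix and the
    next track fix; the bird leaves the site when it crosses the 25 km circle
    around the centroid.  Arrival is symmetric, using the previous track fix.
    Missing neighbours fall back to the member times themselves.
    """
    cfg = cfg or PipelineConfig()
    times, lats, lons = _track_arrays(track, smoothed)
    radius = cfg.site_radius_km

    def _cross(member: StationaryLoc, neighbor_idx: int) -> pd.Timestamp:
        t_m = member.time
        if neighbor_idx < 0 or neighbor_idx >= len(times):
            return t_m
        d_last = float(gc_distance_km(member.lat, member.lon, site.centroid.lat, site.centroid.lon))
        d_seg = float(gc_distance_km(member.lat, member.lon,
                                     lats[neighbor_idx], lons[neighbor_idx]))
        dt = abs((times[neighbor_idx] - t_m).total_seconds())
        if d_seg <= 1e-9:
            if float(gc_distance_km(lats[neighbor_idx], lons[neighbor_idx],
                                    site.centroid.lat, site.centroid.lon)) > radius:
                logger.warning("zero-length segment with neighbour outside radius; "
                               "falling back to the member time")
            return t_m
        frac = min(1.0, max(0.0, (radius - d_last)) / d_seg)
        delta = pd.Timedelta(seconds=dt * frac)
        return t_m + delta if times[neighbor_idx] > t_m else t_m - delta

    last = site.members[-1]
    first = site.members[0]
    departure = _cross(last, last.track_index + 1)
    arrival = _cross(first, first.track_index - 1)
    return arrival, departure


def find_sites(
    track: Track,
    region: Optional[Region],
    cfg: PipelineConfig | None = None,
    season: str = "any",
    smoothed: Optional[SmoothedTrack] = None,
    stationary: Optional[list[StationaryLoc]] = None,
) -> list[StopSite]:
    """Run detect -> cluster -> containment -> merge -> filter -> timing."""
    cfg = cfg or PipelineConfig()
    locs = stationary if stationary is not None else detect_stationary(track, region, cfg, smoothed)
    if not locs:
        return []
    labels = cluster_stationary(locs, cfg)
    labels = enforce_containment(locs, labels, cfg)
    sites = [_make_site(track.individual_id, season,
                        [l for l, lab in zip(locs, labels) if lab == label])
             for label in np.unique(labels)]
    sites = merge_close_sites(sites, cfg)
    sites = filter_sites(sites, cfg)
    for s in sites:
        s.arrival_time, s.departure_time = estimate_times(s, track, cfg, smoothed)
    sites.sort(key=lambda s: s.arrival_time)
    for rank, s in enumerate(sites, start=1):
        s.site_id = f"{track.individual_id}:{season}:{rank}"
    return sites


def build_itinerary(
    track: Track,
    cfg: PipelineConfig | None = None,
    region: Optional[Region] = None,
    smoothed: Optional[SmoothedTrack] = None,
) -> dict[str, list[StopSite]]:
    """Stopover sites per migration season within the staging region.

    The region-resident portion of the track is split into northward and
    southward passage by calendar window; each season is processed
    independently.  Empty seasons yield empty lists.
    """
    cfg = cfg or PipelineConfig()
    if region is None:
        region = cfg.regions["yellow_sea"]
    windows = {"northward": cfg.northward_window, "southward": cfg.southward_window}
    out: dict[str, list[StopSite]] = {}
    all_stationary = detect_stationary(track, region, cfg, smoothed)
    for season, window in windows.items():
        locs = [l for l in all_stationary if month_day_in_window(l.time.date(), window)]
        if not locs:
            out[season] = []
            continue
        if len(locs) > 1:  # consistency check only: net poleward displacement sign
            dlat = locs[-1].lat - locs[0].lat
            expect_north = season == "northward"
            if (dlat > 0) != expect_north and abs(dlat) > 1.0:
                logger.debug("season %s for %s: net displacement sign %.2f deg "
                             "disagrees with calendar window", season, track.individual_id, dlat)
        out[season] = find_sites(track, region, cfg, season=season,
                                 smoothed=smoothed, stationary=locs)
    return out
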