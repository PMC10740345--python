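"""Synthetic telemetry and resighting data with known ground truth.

The generator emulates the statistical structure of a two-species
satellite-tracking and mark-resighting study of migratory shorebirds:

* **Annual cycle** -- austral-summer residency at a Northwest-Australia
  non-breeding site (with a configurable fraction of *movers* that make an
  excursion of 80-920 km to an alternative site mid-season), northward
  passage through 1-4 staging sites along the Yellow Sea coast, Arctic
  breeding residency, and a southward passage that reuses each northward
  staging site with a configurable *revisit* probability.
* **Telemetry** -- Argos-like fixes emitted only during the 8 h-on windows
  of a 33 h duty cycle (8 h transmission / 25 h off), with a location class
  drawn from a configurable mixture and an isotropic position error whose
  radial 68th percentile matches the class accuracy (standard classes
  0.25-1.5 km, auxiliary 5-15 km); occasional large auxiliary-class spikes
  exercise the plausibility filter.  A heavy-tailed (Student-t, df = 4)
  error option exists and is off by default.
* **Resightings** -- scan surveys at a configurable (site, date) schedule;
  an individual present at a surveyed site is recorded with the detection
  probability, and never recorded elsewhere (no false positives).

Truth itineraries are first-class outputs so that every downstream metric
can be checked against known ground truth.  All randomness flows through a
single ``numpy`` generator; the same seed reproduces the dataset exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Fix, PipelineConfig, ResightingRecord, Track
from .geo import GeoPoint, destination_point, gc_distance_km, gc_interpolate
from .io import write_resightings, write_tracks
from .smoother import RAYLEIGH_68

__all__ = [
    "Stay", "TrueItinerary", "SimConfig", "simulate_itinerary",
    "simulate_track", "simulate_resightings", "make_benchmark",
    "paper_like_config", "position_at",
]

#: Non-breeding origin (a Northwest Australia bay) and staging-coast anchors.
ORIGIN = GeoPoint(-18.07, 122.27)
STAGING_BASE = GeoPoint(33.5, 120.8)
STAGING_BEARING_DEG = 28.0          # NNE along the staging coast
BREEDING = GeoPoint(64.5, 174.0)

#: (bearing deg, distance km) templates for non-breeding excursions;
#: distances follow the observed 80-920 km range of within-season moves.
MOVER_TEMPLATES = ((195.0, 80.0), (207.0, 170.0), (205.0, 250.0), (203.0, 320.0), (40.0, 920.0))


@dataclass(frozen=True)
class Stay:
    """One residency bout of the true itinerary."""

    name: str
    lat: float
    lon: float
    start: pd.Timestamp
    end: pd.Timestamp


@dataclass
class TrueItinerary:
    """Ground-truth movement schedule for one individual."""

    individual_id: str
    species: str
    stays: list[Stay]
    origin: GeoPoint
    mover: bool
    n_sites_north: int
    n_sites_south: int
    n_south_revisited: int
    seasonal_revisit: bool

    def __post_init__(self):
        for s1, s2 in zip(self.stays, self.stays[1:]):
            if s2.start < s1.end:
                raise ValueError("itinerary stays overlap in time")


@dataclass
class SimConfig:
    """Study-design parameters of the generator.

    Defaults mirror the study conditions: cohort sizes 24 godwits (BTG) and
    41 knots (GK); 7 of 41 knots and no godwits making a non-breeding
    excursion; godwits revisiting staging sites more often than knots; a
    median of 2 (godwit) vs 3 (knot) northward staging sites.
    """

    n_individuals: dict = field(default_factory=lambda: {"BTG": 24, "GK": 41})
    mover_prob: dict = field(default_factory=lambda: {"BTG": 0.0, "GK": 7 / 41})
    #: exact mover counts per species; overrides mover_prob when not None
    exact_movers: Optional[dict] = None
    revisit_prob: dict = field(default_factory=lambda: {"BTG": 0.85, "GK": 0.6})
    n_sites_north_probs: dict = field(default_factory=lambda: {
        "BTG": {1: 0.25, 2: 0.5, 3: 0.25},
        "GK": {1: 0.10, 2: 0.25, 3: 0.40, 4: 0.25},
    })
    site_sep_km: tuple = (110.0, 240.0)
    stationary_jitter_km: float = 1.5
    fix_interval_h: float = 2.0
    duty_on_h: float = 8.0
    duty_off_h: float = 25.0
    transit_speed_kmh: tuple = (45.0, 65.0)
    class_probs: dict = field(default_factory=lambda: {
        "3": 0.15, "2": 0.20, "1": 0.25, "0": 0.10, "A": 0.15, "B": 0.13, "Z": 0.02,
    })
    class_r68_km: dict = field(default_factory=lambda: {
        "3": 0.25, "2": 0.5, "1": 1.5, "0": 5.0, "A": 8.0, "B": 15.0, "Z": 15.0,
    })
    spike_prob: float = 0.02
    spike_km: tuple = (200.0, 800.0)
    heavy_tailed: bool = False
    with_ellipses: bool = False
    detection_prob: float = 0.8
    full_year: bool = True
    start_year: int = 2015
    first_departure: dict = field(default_factory=lambda: {"GK": (3, 22), "BTG": (4, 4)})
    rng_seed: int = 0

    def validate(self) -> None:
        for d in (self.mover_prob, self.revisit_prob):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"probability out of [0, 1]: {v}")
        if self.fix_interval_h <= 0 or self.stationary_jitter_km < 0:
            raise ValueError("rates and scales must be positive")


def _ts(year: int, month: int, day: int, hours: float = 0.0) -> pd.Timestamp:
    return pd.Timestamp(year=year, month=month, day=day, tz="UTC") + pd.Timedelta(hours=hours)


def _draw_from_probs(probs: dict, rng: np.random.Generator):
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _transit_h(a: GeoPoint, b: GeoPoint, speed_kmh: float) -> float:
    return float(gc_distance_km(a.lat, a.lon, b.lat, b.lon)) / speed_kmh


def _staging_sites(k: int, cfg: SimConfig, rng: np.random.Generator) -> list[GeoPoint]:
    """k staging-site centres along the coast, separated by >= the configured draws."""
    offset = rng.uniform(0.0, 80.0)
    pts = []
    for _ in range(k):
        pts.append(destination_point(STAGING_BASE.lat, STAGING_BASE.lon,
                                     STAGING_BEARING_DEG, offset))
        offset += rng.uniform(*cfg.site_sep_km)
    return pts


def simulate_itinerary(individual_id: str, species: str, cfg: SimConfig,
                       rng: np.random.Generator, mover: Optional[bool] = None) -> TrueItinerary:
    """Draw one individual's true annual (or non-breeding-only) itinerary."""
    cfg.validate()
    if mover is None:
        mover = bool(rng.random() < cfg.mover_prob[species])
    year = cfg.start_year
    release = _ts(year, 10, 1, rng.uniform(0.0, 480.0))   # early-mid October
    dep_m, dep_d = cfg.first_departure[species]
    depart_north = _ts(year + 1, dep_m, dep_d, rng.uniform(0.0, 240.0))
    speed = rng.uniform(*cfg.transit_speed_kmh)

    stays: list[Stay] = []
    if mover:
        brg, dist = MOVER_TEMPLATES[rng.choice(len(MOVER_TEMPLATES))]
        dest = destination_point(ORIGIN.lat, ORIGIN.lon, brg, dist)
        t_leave = release + pd.Timedelta(days=rng.uniform(45.0, 95.0))
        hop = pd.Timedelta(hours=_transit_h(ORIGIN, dest, speed))
        t_arr = t_leave + hop
        if dist >= 900.0:
            # long-distance mover settles at the new site for the season
            stays.append(Stay("origin", ORIGIN.lat, ORIGIN.lon, release, t_leave))
            stays.append(Stay("nb_alt", dest.lat, dest.lon, t_arr, depart_north))
        else:
            t_back = t_arr + pd.Timedelta(days=rng.uniform(12.0, 35.0))
            stays.append(Stay("origin", ORIGIN.lat, ORIGIN.lon, release, t_leave))
            stays.append(Stay("nb_alt", dest.lat, dest.lon, t_arr, t_back))
            stays.append(Stay("origin", ORIGIN.lat, ORIGIN.lon, t_back + hop, depart_north))
    else:
        stays.append(Stay("origin", ORIGIN.lat, ORIGIN.lon, release, depart_north))

    if not cfg.full_year:
        return TrueItinerary(
            individual_id=individual_id, species=species, stays=stays,
            origin=ORIGIN, mover=mover, n_sites_north=0, n_sites_south=0,
            n_south_revisited=0, seasonal_revisit=False,
        )

    # northward staging
    k_n = _draw_from_probs(cfg.n_sites_north_probs[species], rng)
    north_sites = _staging_sites(k_n, cfg, rng)
    last_nb = GeoPoint(stays[-1].lat, stays[-1].lon)
    t = depart_north + pd.Timedelta(hours=_transit_h(last_nb, north_sites[0], speed))
    prev = None
    for i, site in enumerate(north_sites):
        if prev is not None:
            t = t + pd.Timedelta(hours=_transit_h(prev, site, speed))
        dur = pd.Timedelta(days=rng.uniform(8.0, 18.0))
        stays.append(Stay(f"ys_n{i + 1}", site.lat, site.lon, t, t + dur))
        t = t + dur
        prev = site

    # breeding residency
    t_breed = t + pd.Timedelta(hours=_transit_h(prev, BREEDING, speed))
    t_south = _ts(year + 1, 7, 10, rng.uniform(0.0, 360.0))
    if t_south <= t_breed:
        t_south = t_breed + pd.Timedelta(days=20.0)
    stays.append(Stay("breeding", BREEDING.lat, BREEDING.lon, t_breed, t_south))

    # southward staging: each northward site is revisited independently;
    # non-revisited sites are replaced by a fresh site displaced off-coast
    south_sites: list[tuple[GeoPoint, bool]] = []
    for i, site in enumerate(reversed(north_sites)):   # encountered north-to-south
        if rng.random() < cfg.revisit_prob[species]:
            south_sites.append((site, True))
        else:
            alt = destination_point(site.lat, site.lon,
                                    STAGING_BEARING_DEG + 90.0, rng.uniform(60.0, 95.0))
            south_sites.append((alt, False))
    t = t_south + pd.Timedelta(hours=_transit_h(BREEDING, south_sites[0][0], speed))
    prev = None
    for i, (site, revisit) in enumerate(south_sites):
        if prev is not None:
            t = t + pd.Timedelta(hours=_transit_h(prev, site, speed))
        dur = pd.Timedelta(days=rng.uniform(6.0, 16.0))
        stays.append(Stay(f"ys_s{i + 1}", site.lat, site.lon, t, t + dur))
        t = t + dur
        prev = site

    # return to the non-breeding origin
    t_home = t + pd.Timedelta(hours=_transit_h(prev, ORIGIN, speed))
    stays.append(Stay("origin_return", ORIGIN.lat, ORIGIN.lon,
                      t_home, t_home + pd.Timedelta(days=rng.uniform(30.0, 45.0))))

    n_revisited = sum(rev for _, rev in south_sites)
    return TrueItinerary(
        individual_id=individual_id, species=species, stays=stays,
        origin=ORIGIN, mover=mover, n_sites_north=k_n,
        n_sites_south=len(south_sites), n_south_revisited=n_revisited,
        seasonal_revisit=n_revisited > 0,
    )


def position_at(itinerary: TrueItinerary, t: pd.Timestamp) -> GeoPoint:
    """True position at time ``t``: stay centre, or great-circle transit."""
    stays = itinerary.stays
    if t <= stays[0].start:
        return GeoPoint(stays[0].lat, stays[0].lon)
    for i, s in enumerate(stays):
        if s.start <= t <= s.end:
            return GeoPoint(s.lat, s.lon)
        if i + 1 < len(stays) and s.end < t < stays[i + 1].start:
            nxt = stays[i + 1]
            frac = (t - s.end).total_seconds() / (nxt.start - s.end).total_seconds()
            lat, lon = gc_interpolate(s.lat, s.lon, nxt.lat, nxt.lon, np.array([frac]))
            return GeoPoint(float(lat[0]), float(lon[0]))
    return GeoPoint(stays[-1].lat, stays[-1].lon)


def _in_stay(itinerary: TrueItinerary, t: pd.Timestamp) -> bool:
    return any(s.start <= t <= s.end for s in itinerary.stays)


def simulate_track(itinerary: TrueItinerary, cfg: SimConfig,
                   rng: np.random.Generator) -> Track:
    """Emit duty-cycled, class-mixed, error-perturbed fixes along the truth."""
    cfg.validate()
    t0 = itinerary.stays[0].start
    t_end = itinerary.stays[-1].end
    cycle_h = cfg.duty_on_h + cfg.duty_off_h
    phase_h = rng.uniform(0.0, cycle_h)
    classes = sorted(cfg.class_probs)
    probs = np.array([cfg.class_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    fix_times: list[pd.Timestamp] = []
    window_start = t0 + pd.Timedelta(hours=phase_h)
    while window_start < t_end:
        h = rng.uniform(0.0, 0.5)
        while h < cfg.duty_on_h:
            ft = window_start + pd.Timedelta(hours=h)
            if t0 <= ft <= t_end:
                fix_times.append(ft)
            h += cfg.fix_interval_h
        window_start = window_start + pd.Timedelta(hours=cycle_h)

    fixes: list[Fix] = []
    for ft in fix_times:
        true = position_at(itinerary, ft)
        if _in_stay(itinerary, ft) and cfg.stationary_jitter_km > 0:
            true = destination_point(true.lat, true.lon, rng.uniform(0.0, 360.0),
                                     abs(rng.normal(0.0, cfg.stationary_jitter_km)))
        loc_class = classes[rng.choice(len(classes), p=probs)]
        r68 = cfg.class_r68_km[loc_class]
        sigma = r68 / RAYLEIGH_68
        if loc_class not in ("3", "2", "1") and rng.random() < cfg.spike_prob:
            err_km = rng.uniform(*cfg.spike_km)
        else:
            e, n = rng.normal(0.0, sigma, size=2)
            if cfg.heavy_tailed:
                scale = math.sqrt(4.0 / rng.chisquare(4.0))
                e, n = e * scale, n * scale
            err_km = math.hypot(e, n)
        obs = destination_point(true.lat, true.lon, rng.uniform(0.0, 360.0), err_km) \
            if err_km > 0 else true
        smaj = smin = eor = None
        if cfg.with_ellipses:
            smaj = smin = sigma * 1000.0
            eor = 0.0
        fixes.append(Fix(
            individual_id=itinerary.individual_id, timestamp=ft,
            lat=obs.lat, lon=obs.lon, loc_class=loc_class,
            ellipse_semi_major_m=smaj, ellipse_semi_minor_m=smin,
            ellipse_orientation_deg=eor,
        ))
    return Track(individual_id=itinerary.individual_id, species=itinerary.species,
                 fixes=fixes, release_time=t0)


def default_survey_schedule(itineraries: Sequence[TrueItinerary],
                            sites: Optional[Sequence[tuple[str, float, float]]] = None,
                            every_days: int = 7) -> list[tuple[str, float, float, pd.Timestamp]]:
    """Weekly surveys at the given sites (default: the origin only) over the study span."""
    if sites is None:
        sites = [("origin", ORIGIN.lat, ORIGIN.lon)]
    t_min = min(it.stays[0].start for it in itineraries)
    t_max = max(it.stays[-1].end for it in itineraries)
    schedule = []
    t = t_min.normalize() + pd.Timedelta(hours=12)
    while t <= t_max:
        for name, lat, lon in sites:
            schedule.append((name, lat, lon, t))
        t += pd.Timedelta(days=every_days)
    return schedule


def simulate_resightings(
    itineraries: Sequence[TrueItinerary],
    cfg: SimConfig,
    rng: np.random.Generator,
    schedule: Optional[Sequence[tuple[str, float, float, pd.Timestamp]]] = None,
    presence_radius_km: float = 25.0,
) -> list[ResightingRecord]:
    """Survey-based detections: present individuals recorded with probability
    ``detection_prob``; absent individuals never recorded."""
    cfg.validate()
    if schedule is None:
        schedule = default_survey_schedule(itineraries)
    records: list[ResightingRecord] = []
    for it in itineraries:
        for name, lat, lon, t in schedule:
            if not it.stays[0].start <= t <= it.stays[-1].end:
                continue
            pos = position_at(it, t)
            if float(gc_distance_km(pos.lat, pos.lon, lat, lon)) > presence_radius_km:
                continue
            if rng.random() < cfg.detection_prob:
                records.append(ResightingRecord(
                    individual_id=it.individual_id, species=it.species,
                    date=t.date(), site_id=name, site_lat=lat, site_lon=lon,
                ))
    return records


def _assign_movers(cfg: SimConfig, species: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.exact_movers is not None:
        k = int(cfg.exact_movers.get(species, 0))
        flags = np.zeros(n, dtype=bool)
        flags[rng.choice(n, size=k, replace=False)] = True
        return flags
    return rng.random(n) < cfg.mover_prob[species]


def make_benchmark(cfg: SimConfig, outdir: Optional[str] = None, seed: Optional[int] = None):
    """Generate the full bundle: tracks, resightings and truth tables.

    Returns a dict with ``itineraries``, ``tracks``, ``resightings`` and a
    ``truth`` DataFrame; when ``outdir`` is given, writes ``telemetry.csv``,
    ``resightings.csv`` and ``truth_individuals.csv`` there.  Byte-identical
    given the same seed and config.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    itineraries: list[TrueItinerary] = []
    tracks: list[Track] = []
    for species in sorted(cfg.n_individuals):
        n = cfg.n_individuals[species]
        movers = _assign_movers(cfg, species, n, rng)
        for i in range(n):
            ind = f"{species}{i + 1:03d}"
            it = simulate_itinerary(ind, species, cfg, rng, mover=bool(movers[i]))
            itineraries.append(it)
            tracks.append(simulate_track(it, cfg, rng))
    records = simulate_resightings(itineraries, cfg, rng)
    truth = pd.DataFrame([{
        "individual_id": it.individual_id, "species": it.species,
        "mover": it.mover, "n_sites_north": it.n_sites_north,
        "n_sites_south": it.n_sites_south,
        "n_south_revisited": it.n_south_revisited,
        "seasonal_revisit": it.seasonal_revisit,
        "origin_lat": it.origin.lat, "origin_lon": it.origin.lon,
    } for it in itineraries])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tracks(tracks, outdir / "telemetry.csv")
        write_resightings(records, outdir / "resightings.csv")
        truth.to_csv(outdir / "truth_individuals.csv", index=False)
    return {"itineraries": itineraries, "tracks": tracks,
            "resightings": records, "truth": truth}


def paper_like_config(seed: int = 0) -> SimConfig:
    """The study-design preset: 24 + 41 individuals, exactly 7 knot movers,
    non-breeding season only (the Table-1 analogue cohort)."""
    return SimConfig(
        n_individuals={"BTG": 24, "GK": 41},
        exact_movers={"BTG": 0, "GK": 7},
        full_year=False,
        rng_seed=seed,
    )
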