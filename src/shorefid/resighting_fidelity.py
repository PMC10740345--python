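"""Mark-resighting site-fidelity metrics.

Resightings are binned into periods: *non-breeding* (1 November until a
week before the species' first tracked departure), or *northward* /
*southward* migration when the record falls inside the staging-region
(Yellow Sea) calendar windows and the site lies inside that region.  Only
individuals with two or more sightings in a period contribute; an individual
resighted in several years is collapsed to a single datapoint (the maximum
site count over its qualifying periods) to avoid pseudo-replication.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional

from .core import Contingency2x2, PipelineConfig, ResightingRecord, logger, month_day_in_window
from .geo import gc_distance_km, point_in_region

__all__ = [
    "PeriodKey", "PeriodUsage", "assign_period", "period_usage",
    "collapse_across_years", "seasonal_match", "between_year_match",
    "resight_summary",
]


@dataclass(frozen=True)
class PeriodKey:
    """One individual's period: non-breeding, northward or southward, by year.

    The non-breeding period year is the year containing its 1 November.
    """

    individual_id: str
    period_type: str    # "nonbreeding" | "northward" | "southward"
    period_year: int


@dataclass(frozen=True)
class PeriodUsage:
    """Sighting and distinct-site counts in one qualifying period."""

    key: PeriodKey
    n_sightings: int
    n_sites: int
    site_ids: tuple
    site_coords: tuple   # ((lat, lon), ...) parallel to site_ids


def assign_period(record: ResightingRecord, cfg: PipelineConfig | None = None) -> Optional[PeriodKey]:
    """Classify one record into a period, or ``None`` when it fits none.

    Staging-region migration records take precedence over the non-breeding
    calendar (the southward window and the non-breeding window overlap in
    November, but a bird seen in the Yellow Sea is on passage).
    """
    cfg = cfg or PipelineConfig()
    date = record.date
    staging = cfg.regions["yellow_sea"]
    if point_in_region(record.site_lat, record.site_lon, staging.polygon):
        if month_day_in_window(date, cfg.northward_window):
            return PeriodKey(record.individual_id, "northward", date.year)
        if month_day_in_window(date, cfg.southward_window):
            return PeriodKey(record.individual_id, "southward", date.year)
        return None
    if record.species not in cfg.first_departure:
        return None
    dep_m, dep_d = cfg.first_departure[record.species]
    end = (dt.date(2000, dep_m, dep_d) - dt.timedelta(days=cfg.departure_buffer_days))
    window = (cfg.nonbreeding_resight_start, (end.month, end.day))
    if month_day_in_window(date, window):
        start_m, _ = cfg.nonbreeding_resight_start
        year = date.year if date.month >= start_m else date.year - 1
        return PeriodKey(record.individual_id, "nonbreeding", year)
    return None


def period_usage(records: list[ResightingRecord],
                 cfg: PipelineConfig | None = None) -> list[PeriodUsage]:
    """Per-(individual, period) sighting and site counts; < 2 sightings dropped."""
    cfg = cfg or PipelineConfig()
    buckets: dict[PeriodKey, list[ResightingRecord]] = defaultdict(list)
    for rec in records:
        key = assign_period(rec, cfg)
        if key is not None:
            buckets[key].append(rec)
    out = []
    for key, recs in buckets.items():
        if len(recs) < cfg.min_sightings:
            continue
        sites: dict[str, tuple] = {}
        for r in recs:
            sites.setdefault(r.site_id, (r.site_lat, r.site_lon))
        out.append(PeriodUsage(
            key=key, n_sightings=len(recs), n_sites=len(sites),
            site_ids=tuple(sorted(sites)),
            site_coords=tuple(sites[sid] for sid in sorted(sites)),
        ))
    return out


def collapse_across_years(usages: list[PeriodUsage], period_type: str) -> dict[str, int]:
    """One value per individual: max site count over its qualifying periods."""
    best: dict[str, int] = {}
    for u in usages:
        if u.key.period_type != period_type:
            continue
        ind = u.key.individual_id
        best[ind] = max(best.get(ind, 0), u.n_sites)
    return best


def _sites_match(id1, coord1, id2, coord2, revisit_km: float) -> bool:
    if id1 == id2:
        return True
    d = float(gc_distance_km(coord1[0], coord1[1], coord2[0], coord2[1]))
    return d <= revisit_km


def seasonal_match(records: list[ResightingRecord],
                   cfg: PipelineConfig | None = None) -> dict[str, bool]:
    """Per individual: seen at the same staging site in both migration seasons.

    Computed per year and pooled across years (an individual is a match if
    any year matches), mirroring the pooled treatment of multi-year
    resighting histories.  Only individuals with at least one northward and
    one southward staging record in the same year enter the result.
    """
    cfg = cfg or PipelineConfig()
    by_ind_year: dict[tuple, dict[str, dict]] = defaultdict(lambda: {"northward": {}, "southward": {}})
    for rec in records:
        key = assign_period(rec, cfg)
        if key is None or key.period_type not in ("northward", "southward"):
            continue
        by_ind_year[(key.individual_id, key.period_year)][key.period_type].setdefault(
            rec.site_id, (rec.site_lat, rec.site_lon))
    out: dict[str, bool] = {}
    for (ind, _year), seasons in sorted(by_ind_year.items()):
        north, south = seasons["northward"], seasons["southward"]
        if not north or not south:
            continue
        matched = any(
            _sites_match(nid, ncoord, sid, scoord, cfg.revisit_km)
            for nid, ncoord in north.items() for sid, scoord in south.items()
        )
        out[ind] = out.get(ind, False) or matched
    return out


def between_year_match(records: list[ResightingRecord],
                       cfg: PipelineConfig | None = None) -> dict[str, bool]:
    """Per individual: same staging site used in >= 2 distinct northward seasons.

    Individuals seen in only one northward season are excluded from the
    denominator.
    """
    cfg = cfg or PipelineConfig()
    by_ind: dict[str, dict[int, dict]] = defaultdict(dict)
    for rec in records:
        key = assign_period(rec, cfg)
        if key is None or key.period_type != "northward":
            continue
        by_ind[rec.individual_id].setdefault(key.period_year, {}).setdefault(
            rec.site_id, (rec.site_lat, rec.site_lon))
    out: dict[str, bool] = {}
    for ind, years in by_ind.items():
        if len(years) < 2:
            continue
        matched = False
        year_list = sorted(years)
        for i, y1 in enumerate(year_list):
            for y2 in year_list[i + 1:]:
                if any(
                    _sites_match(id1, c1, id2, c2, cfg.revisit_km)
                    for id1, c1 in years[y1].items() for id2, c2 in years[y2].items()
                ):
                    matched = True
        out[ind] = matched
    return out


def _split_by_species(records, mapping: dict[str, bool | int]) -> dict[str, dict]:
    species_of = {r.individual_id: r.species for r in records}
    out: dict[str, dict] = defaultdict(dict)
    for ind, value in mapping.items():
        out[species_of[ind]][ind] = value
    return out


def resight_summary(records: list[ResightingRecord],
                    cfg: PipelineConfig | None = None,
                    species_pair: tuple[str, str] = ("BTG", "GK")) -> dict:
    """Cohort summary of the resighting metrics, with 2x2 tables.

    Three dichotomies are tabulated (rows ordered as ``species_pair``):
    one vs >= 2 non-breeding sites; seasonal staging-site match vs not;
    between-year northward match vs not.  Percentages are exact count
    ratios.  Each individual contributes at most one datapoint per table.
    """
    cfg = cfg or PipelineConfig()
    sp1, sp2 = species_pair
    usages = period_usage(records, cfg)
    out: dict = {"species_pair": species_pair}

    nb = collapse_across_years(usages, "nonbreeding")
    nb_by_sp = _split_by_species(records, nb)
    sec = {}
    for sp in species_pair:
        vals = list(nb_by_sp.get(sp, {}).values())
        n = len(vals)
        multi = sum(v >= 2 for v in vals)
        sec[sp] = {"n": n, "one_site": n - multi, "multi_site": multi,
                   "pct_one_site": 100.0 * (n - multi) / n if n else float("nan")}
    if all(sec[sp]["n"] for sp in species_pair):
        sec["table"] = Contingency2x2(
            a=sec[sp1]["one_site"], b=sec[sp1]["multi_site"],
            c=sec[sp2]["one_site"], d=sec[sp2]["multi_site"])
    out["nonbreeding_sites"] = sec

    nw = collapse_across_years(usages, "northward")
    nw_by_sp = _split_by_species(records, nw)
    sec = {}
    for sp in species_pair:
        vals = list(nw_by_sp.get(sp, {}).values())
        n = len(vals)
        multi = sum(v >= 2 for v in vals)
        sec[sp] = {"n": n, "one_site": n - multi, "multi_site": multi,
                   "pct_one_site": 100.0 * (n - multi) / n if n else float("nan")}
    if all(sec[sp]["n"] for sp in species_pair):
        sec["table"] = Contingency2x2(
            a=sec[sp1]["one_site"], b=sec[sp1]["multi_site"],
            c=sec[sp2]["one_site"], d=sec[sp2]["multi_site"])
    out["northward_sites"] = sec

    for name, mapping in (("seasonal_match", seasonal_match(records, cfg)),
                          ("between_year_match", between_year_match(records, cfg))):
        by_sp = _split_by_species(records, mapping)
        sec = {}
        for sp in species_pair:
            vals = list(by_sp.get(sp, {}).values())
            n = len(vals)
            match = sum(vals)
            sec[sp] = {"n": n, "matched": match,
                       "pct_matched": 100.0 * match / n if n else float("nan")}
        if all(sec[sp]["n"] for sp in species_pair):
            sec["table"] = Contingency2x2(
                a=sec[sp1]["matched"], b=sec[sp1]["n"] - sec[sp1]["matched"],
                c=sec[sp2]["matched"], d=sec[sp2]["n"] - sec[sp2]["matched"])
        out[name] = sec
    return out
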