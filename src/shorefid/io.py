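"""Readers and writers for telemetry, resighting and site tables.

Telemetry CSV columns: ``individual_id, species, timestamp, lat, lon,
loc_class, smaj_m, smin_m, eor_deg`` (the last three optional).  Resighting
CSV columns: ``individual_id, species, date, site_id, site_lat, site_lon``.
Site tables are written as CSV (fixed column order, coordinates at 6 decimal
places) or RFC 7946 GeoJSON.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .core import Fix, ResightingRecord, Track, class_rank, logger

TELEMETRY_REQUIRED = ("individual_id", "timestamp", "lat", "lon", "loc_class")
RESIGHT_REQUIRED = ("individual_id", "species", "date", "site_lat", "site_lon")

#: Fixed column order of the site CSV.
SITE_COLUMNS = (
    "site_id", "individual_id", "season", "centroid_lat", "centroid_lon",
    "n_locs", "first_time", "last_time", "arrival_time", "departure_time",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowError(ValueError):
    """A row could not be parsed; the message carries the 1-based line number."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _parse_optional_float(value):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_tracks(path, species_default: str = "UNK") -> list[Track]:
    """Read a telemetry CSV into one :class:`Track` per individual.

    Fixes are grouped by individual and sorted by time; rows with exactly
    equal timestamps are collapsed keeping the best location class
    (3 > 2 > 1 > 0 > A > B > Z; ties keep the first row in file order).
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "loc_class": str})
    _require_columns(df, TELEMETRY_REQUIRED, path)
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        # fall back to row-wise parsing to report the offending line
        for i, raw in enumerate(df["timestamp"]):
            try:
                pd.Timestamp(raw).tz_localize(None)
            except (ValueError, TypeError) as exc:
                raise RowError(f"{path}, line {i + 2}: unparseable timestamp {raw!r}") from exc
        raise
    tracks: list[Track] = []
    for ind, g in df.groupby("individual_id", sort=True):
        g = g.sort_values("timestamp", kind="stable")
        fixes: list[Fix] = []
        for row in g.itertuples():
            line_no = row.Index + 2  # header + 1-based
            loc_class = str(row.loc_class).strip().upper()
            if loc_class not in "3210ABZ" or len(loc_class) != 1:
                raise RowError(f"{path}, line {line_no}: bad location class {row.loc_class!r}")
            try:
                fix = Fix(
                    individual_id=str(ind),
                    timestamp=row.timestamp,
                    lat=float(row.lat),
                    lon=float(row.lon),
                    loc_class=loc_class,
                    ellipse_semi_major_m=_parse_optional_float(getattr(row, "smaj_m", None)),
                    ellipse_semi_minor_m=_parse_optional_float(getattr(row, "smin_m", None)),
                    ellipse_orientation_deg=_parse_optional_float(getattr(row, "eor_deg", None)),
                )
            except ValueError as exc:
                raise RowError(f"{path}, line {line_no}: {exc}") from exc
            if fixes and fix.timestamp == fixes[-1].timestamp:
                if class_rank(fix.loc_class) < class_rank(fixes[-1].loc_class):
                    fixes[-1] = fix
                else:
                    logger.debug(
                        "duplicate timestamp %s for %s: keeping earlier row (class %s)",
                        fix.timestamp, ind, fixes[-1].loc_class,
                    )
                continue
            fixes.append(fix)
        species = species_default
        if "species" in g.columns and len(g):
            species = str(g["species"].iloc[0])
        tracks.append(Track(individual_id=str(ind), species=species, fixes=fixes))
    return tracks


def synthesize_site_id(lat: float, lon: float, grid_deg: float = 0.25) -> str:
    """Stable site id from coordinates snapped to a grid (~27 km at 0.25 deg)."""
    glat = round(lat / grid_deg) * grid_deg
    glon = round(lon / grid_deg) * grid_deg
    return f"site_{glat:+08.2f}_{glon:+09.2f}"


def read_resightings(path, grid_deg: float = 0.25) -> list[ResightingRecord]:
    """Read a resighting CSV; duplicate (individual, site, date) rows collapse to one."""
    df = pd.read_csv(path, dtype={"individual_id": str, "site_id": str})
    _require_columns(df, RESIGHT_REQUIRED, path)
    records: dict[tuple, ResightingRecord] = {}
    for row in df.itertuples():
        line_no = row.Index + 2
        try:
            date = pd.Timestamp(row.date).date()
        except (ValueError, TypeError) as exc:
            raise RowError(f"{path}, line {line_no}: unparseable date {row.date!r}") from exc
        lat, lon = float(row.site_lat), float(row.site_lon)
        site_id = getattr(row, "site_id", None)
        if site_id is None or (isinstance(site_id, float) and math.isnan(site_id)) or site_id == "":
            site_id = synthesize_site_id(lat, lon, grid_deg)
        rec = ResightingRecord(
            individual_id=str(row.individual_id), species=str(row.species),
            date=date, site_id=str(site_id), site_lat=lat, site_lon=lon,
        )
        records.setdefault((rec.individual_id, rec.site_id, rec.date), rec)
    return list(records.values())


def _site_row(site) -> dict:
    return {
        "site_id": site.site_id,
        "individual_id": site.individual_id,
        "season": site.season,
        "centroid_lat": round(site.centroid.lat, 6),
        "centroid_lon": round(site.centroid.lon, 6),
        "n_locs": len(site.members),
        "first_time": site.first_time.isoformat(),
        "last_time": site.last_time.isoformat(),
        "arrival_time": site.arrival_time.isoformat(),
        "departure_time": site.departure_time.isoformat(),
    }


def write_sites(sites, path, fmt: str = "csv") -> None:
    """Write stop sites as CSV (documented column order) or GeoJSON points."""
    path = Path(path)
    if fmt.lower() == "csv":
        df = pd.DataFrame([_site_row(s) for s in sites], columns=SITE_COLUMNS)
        df.to_csv(path, index=False)
    elif fmt.lower() == "geojson":
        features = []
        for s in sites:
            props = _site_row(s)
            lon = props.pop("centroid_lon")
            lat = props.pop("centroid_lat")
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [lon, lat]},
                "properties": props,
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
    else:
        raise ValueError(f"unknown site output format: {fmt!r}")


def read_sites(path) -> pd.DataFrame:
    """Read a site CSV back into a DataFrame (round-trip partner of write_sites)."""
    return pd.read_csv(path, dtype={"site_id": str, "individual_id": str})


def write_tracks(tracks, path) -> None:
    """Write tracks to the telemetry CSV schema."""
    rows = []
    for tr in tracks:
        for f in tr.fixes:
            rows.append({
                "individual_id": f.individual_id,
                "species": tr.species,
                "timestamp": f.timestamp.isoformat(),
                "lat": round(f.lat, 6),
                "lon": round(f.lon, 6),
                "loc_class": f.loc_class,
                "smaj_m": f.ellipse_semi_major_m,
                "smin_m": f.ellipse_semi_minor_m,
                "eor_deg": f.ellipse_orientation_deg,
            })
    cols = ["individual_id", "species", "timestamp", "lat", "lon", "loc_class",
            "smaj_m", "smin_m", "eor_deg"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_resightings(records, path) -> None:
    rows = [{
        "individual_id": r.individual_id, "species": r.species,
        "date": r.date.isoformat(), "site_id": r.site_id,
        "site_lat": round(r.site_lat, 6), "site_lon": round(r.site_lon, 6),
    } for r in records]
    cols = ["individual_id", "species", "date", "site_id", "site_lat", "site_lon"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
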