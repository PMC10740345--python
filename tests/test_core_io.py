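import datetime as dt

import pandas as pd
import pytest

from shorefid import Contingency2x2, Fix, PipelineConfig, Track
from shorefid.core import month_day_in_window
from shorefid.io import (
    RowError,
    SchemaError,
    read_resightings,
    read_sites,
    read_tracks,
    synthesize_site_id,
    write_resightings,
    write_sites,
    write_tracks,
)
from shorefid.stopover import StationaryLoc, StopSite
from shorefid.geo import GeoPoint

from helpers import T0, fix, track


class TestFixValidation:
    def test_latitude_out_of_range(self):
        with pytest.raises(ValueError):
            fix(lat=91.0)

    def test_longitude_normalized(self):
        assert fix(lon=190.0).lon == pytest.approx(-170.0)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            fix(lc="G")

    def test_ellipse_axis_ordering(self):
        with pytest.raises(ValueError):
            fix(ellipse_semi_major_m=100.0, ellipse_semi_minor_m=200.0)

    def test_track_requires_increasing_time(self):
        with pytest.raises(ValueError):
            Track("b1", "GK", [fix(hours=1.0), fix(hours=0.0)])


class TestContingency:
    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            Contingency2x2(1, -1, 0, 0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            Contingency2x2(0, 0, 0, 0)


TELEMETRY = """individual_id,species,timestamp,lat,lon,loc_class
b1,GK,2016-01-05T00:00:00+00:00,-18.1,122.3,3
b1,GK,2016-01-05T02:00:00+00:00,-18.2,122.4,2
b1,GK,2016-01-05T04:00:00+00:00,-18.3,122.5,B
"""


class TestReadTracks:
    def test_well_formed_csv_identity(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(TELEMETRY)
        tracks = read_tracks(p)
        assert len(tracks) == 1
        assert len(tracks[0]) == 3
        assert tracks[0].species == "GK"
        assert [f.loc_class for f in tracks[0].fixes] == ["3", "2", "B"]

    def test_duplicate_timestamp_keeps_better_class(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "individual_id,timestamp,lat,lon,loc_class\n"
            "b1,2016-01-05T00:00:00+00:00,-18.1,122.3,B\n"
            "b1,2016-01-05T00:00:00+00:00,-18.2,122.4,2\n"
        )
        tracks = read_tracks(p)
        assert len(tracks[0]) == 1
        assert tracks[0].fixes[0].loc_class == "2"

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("individual_id,timestamp,lat,lon\nb1,2016-01-05,0,0\n")
        with pytest.raises(SchemaError, match="loc_class"):
            read_tracks(p)

    def test_bad_class_reports_line_number(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "individual_id,timestamp,lat,lon,loc_class\n"
            "b1,2016-01-05T00:00:00+00:00,-18.1,122.3,3\n"
            "b1,2016-01-05T01:00:00+00:00,-18.1,122.3,Q\n"
        )
        with pytest.raises(RowError, match="line 3"):
            read_tracks(p)

    def test_row_order_permutation_invariant(self, tmp_path):
        lines = TELEMETRY.strip().split("\n")
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        p1.write_text("\n".join(lines) + "\n")
        p2.write_text("\n".join([lines[0], lines[3], lines[1], lines[2]]) + "\n")
        t1, t2 = read_tracks(p1)[0], read_tracks(p2)[0]
        assert [f.timestamp for f in t1.fixes] == [f.timestamp for f in t2.fixes]
        assert all(a.timestamp < b.timestamp for a, b in zip(t1.fixes, t1.fixes[1:]))

    def test_round_trip(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(TELEMETRY)
        tracks = read_tracks(p)
        q = tmp_path / "u.csv"
        write_tracks(tracks, q)
        again = read_tracks(q)
        assert [(f.timestamp, f.lat, f.lon, f.loc_class) for f in tracks[0].fixes] == \
               [(f.timestamp, f.lat, f.lon, f.loc_class) for f in again[0].fixes]


RESIGHT = """individual_id,species,date,site_id,site_lat,site_lon
r1,BTG,2012-01-10,RB,-18.07,122.27
r1,BTG,2012-01-10,RB,-18.07,122.27
r2,GK,2012-01-12,,-19.40,121.30
"""


class TestReadResightings:
    def test_duplicates_collapse(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(RESIGHT)
        recs = read_resightings(p)
        assert len(recs) == 2

    def test_site_id_synthesized_and_stable(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(RESIGHT)
        recs = {r.individual_id: r for r in read_resightings(p)}
        sid = recs["r2"].site_id
        assert sid == synthesize_site_id(-19.40, 121.30)
        # round-trip: write then read keeps the same id
        q = tmp_path / "r2.csv"
        write_resightings(list(recs.values()), q)
        again = {r.individual_id: r for r in read_resightings(q)}
        assert again["r2"].site_id == sid

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("individual_id,species,date,site_id,site_lat,site_lon\n")
        assert read_resightings(p) == []


def _site(ind="b1", season="northward"):
    members = [
        StationaryLoc(ind, T0 + pd.Timedelta(hours=h), 34.0, 121.0, 1.0, i)
        for i, h in enumerate((0.0, 2.0, 5.0))
    ]
    return StopSite(site_id=f"{ind}:{season}:1", individual_id=ind, season=season,
                    centroid=GeoPoint(34.0, 121.0), members=members)


class TestWriteSites:
    def test_csv_round_trip(self, tmp_path):
        s = _site()
        p = tmp_path / "s.csv"
        write_sites([s], p, "csv")
        df = read_sites(p)
        assert len(df) == 1
        assert df.loc[0, "site_id"] == s.site_id
        assert df.loc[0, "n_locs"] == 3
        assert df.loc[0, "centroid_lat"] == pytest.approx(34.0, abs=1e-6)
        # writing the read-back table again is byte-identical
        q = tmp_path / "s2.csv"
        df.to_csv(q, index=False)
        assert p.read_text() == q.read_text()

    def test_geojson_feature(self, tmp_path):
        import json
        p = tmp_path / "s.geojson"
        write_sites([_site()], p, "geojson")
        gj = json.loads(p.read_text())
        assert gj["type"] == "FeatureCollection"
        assert len(gj["features"]) == 1
        feat = gj["features"][0]
        assert feat["geometry"]["coordinates"] == [121.0, 34.0]
        assert feat["properties"]["n_locs"] == 3
        assert feat["properties"]["season"] == "northward"

    def test_empty_feature_collection(self, tmp_path):
        import json
        p = tmp_path / "s.geojson"
        write_sites([], p, "geojson")
        assert json.loads(p.read_text())["features"] == []


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(vmax_kmh=100.0, merge_km=60.0)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        again = PipelineConfig.from_yaml(p)
        assert again.vmax_kmh == 100.0
        assert again.merge_km == 60.0
        assert again.first_departure == cfg.first_departure
        assert set(again.regions) == set(cfg.regions)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(containment_frac=1.5)
        with pytest.raises(ValueError):
            PipelineConfig(merge_km=-1.0)


def test_calendar_window_wraps_year_boundary():
    window = ((11, 1), (3, 15))
    assert month_day_in_window(dt.date(2015, 12, 25), window)
    assert month_day_in_window(dt.date(2016, 2, 1), window)
    assert not month_day_in_window(dt.date(2016, 5, 1), window)
    assert month_day_in_window(dt.date(2016, 4, 1), ((3, 1), (6, 30)))
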