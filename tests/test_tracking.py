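"""Track I/O, QC screening, AGL derivation and step kinematics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hs

import soartrack as st
from soartrack.dem import DemCoverageError


def make_track(seconds, lon, lat, alt, speed=None, nsat=None, dop=None,
               t0="2012-06-15 10:00:00", interval=1.0):
    n = len(seconds)
    fixes = pd.DataFrame({
        "timestamp": pd.Timestamp(t0) + pd.to_timedelta(seconds, unit="s"),
        "lon": lon, "lat": lat, "gps_altitude": alt,
        "speed": speed if speed is not None else np.nan,
        "n_satellites": nsat if nsat is not None else np.nan,
        "dop": dop if dop is not None else np.nan,
        "agl": np.nan,
    })
    return st.Track("bird", fixes, interval)


class TestReadTrack:
    def write_csv(self, tmp_path, rows, header=None):
        header = header or ("individual-local-identifier,timestamp,location-long,"
                            "location-lat,height-above-msl,ground-speed,"
                            "gps-satellite-count,gps-dop")
        p = tmp_path / "track.csv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def test_well_formed_csv(self, tmp_path):
        rows = [f"kes,2012-06-15 10:00:0{i},-6.05,37.35,80,5.0,8,1.2" for i in range(3)]
        track = st.read_track(self.write_csv(tmp_path, rows))
        assert len(track) == 3
        assert track.sampling_interval == 1
        assert track.individual_id == "kes"

    def test_out_of_order_rows_sorted(self, tmp_path):
        rows = ["kes,2012-06-15 10:00:02,-6.05,37.35,82,5.0,8,1.2",
                "kes,2012-06-15 10:00:00,-6.05,37.35,80,5.0,8,1.2",
                "kes,2012-06-15 10:00:01,-6.05,37.35,81,5.0,8,1.2"]
        track = st.read_track(self.write_csv(tmp_path, rows))
        assert track.fixes["timestamp"].is_monotonic_increasing
        assert list(track.fixes["gps_altitude"]) == [80, 81, 82]

    def test_duplicate_timestamps_keep_first(self, tmp_path):
        rows = ["kes,2012-06-15 10:00:00,-6.05,37.35,80,5.0,8,1.2",
                "kes,2012-06-15 10:00:00,-6.05,37.35,99,5.0,8,1.2",
                "kes,2012-06-15 10:00:01,-6.05,37.35,81,5.0,8,1.2"]
        track = st.read_track(self.write_csv(tmp_path, rows))
        assert len(track) == 2
        assert track.fixes["gps_altitude"].iloc[0] == 80

    def test_missing_required_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("timestamp,location-long\n2012-06-15 10:00:00,-6.05\n")
        with pytest.raises(st.TrackFormatError):
            st.read_track(p)

    def test_empty_file(self, tmp_path):
        p = self.write_csv(tmp_path, [])
        with pytest.raises(st.TrackFormatError):
            st.read_track(p)

    def test_interval_mode_snapping(self):
        # gaps of 59-61 s snap to the 60-s interval
        gaps = [59, 60, 61, 60, 59]
        seconds = np.concatenate([[0], np.cumsum(gaps)])
        ts = pd.Timestamp("2012-06-15") + pd.to_timedelta(seconds, unit="s")
        assert st.infer_sampling_interval(pd.Series(ts)) == 60

    def test_roundtrip(self, tmp_path):
        track = make_track(np.arange(5), np.linspace(-6.05, -6.04, 5),
                           np.full(5, 37.35), np.linspace(80, 90, 5),
                           speed=np.full(5, 5.0), nsat=np.full(5, 8.0),
                           dop=np.full(5, 1.2))
        st.write_track(track, tmp_path / "t.csv")
        back = st.read_track(tmp_path / "t.csv")
        np.testing.assert_allclose(back.fixes["lon"], track.fixes["lon"])
        np.testing.assert_allclose(back.fixes["gps_altitude"],
                                   track.fixes["gps_altitude"])


class TestQcFilter:
    def test_satellite_and_dop_rules(self):
        track = make_track(np.arange(4), [-6.05] * 4, [37.35] * 4, [80] * 4,
                           nsat=[3, 4, 8, 8], dop=[1.0, 1.0, 3.0, 3.1])
        out, rep = st.qc_filter(track)
        # n_sat = 3 removed; dop 3.0 retained, 3.1 removed (strictly over)
        assert len(out) == 2
        assert rep.few_satellites == 1 and rep.high_dop == 1
        assert rep.n_in == 4 and rep.n_out == 2

    def test_no_quality_columns_pass(self):
        track = make_track(np.arange(3), [-6.05] * 3, [37.35] * 3, [80] * 3)
        out, rep = st.qc_filter(track)
        assert len(out) == 3
        assert rep.n_removed == 0

    @given(nsat=hs.lists(hs.integers(0, 12), min_size=1, max_size=40),
           dop=hs.floats(0.5, 6.0))
    def test_count_conservation(self, nsat, dop):
        n = len(nsat)
        track = make_track(np.arange(n), [-6.05] * n, [37.35] * n, [80] * n,
                           nsat=np.array(nsat, float),
                           dop=np.full(n, dop))
        out, rep = st.qc_filter(track)
        assert rep.n_in - rep.n_out == rep.n_removed
        assert rep.n_out == len(out)


class TestAttachAgl:
    dem = st.make_dem(-6.1, -6.0, 37.3, 37.4, cellsize_deg=0.01,
                      base_elevation_m=50.0)

    def test_subtraction(self):
        track = make_track([0], [-6.05], [37.35], [150.0])
        out, _ = st.attach_agl(track, self.dem)
        assert out.fixes["agl"].iloc[0] == pytest.approx(100.0)

    def test_negative_agl_removed(self):
        track = make_track([0, 1], [-6.05, -6.05], [37.35, 37.35], [40.0, 150.0])
        out, rep = st.attach_agl(track, self.dem)
        assert len(out) == 1
        assert rep.negative_altitude == 1

    def test_raw_rule_keeps_positive_gps_altitude(self):
        track = make_track([0], [-6.05], [37.35], [40.0])
        out, rep = st.attach_agl(track, self.dem, negative_rule="raw")
        assert len(out) == 1 and rep.negative_altitude == 0

    def test_nodata_cell_raises(self):
        dem = st.make_dem(-6.1, -6.0, 37.3, 37.4, cellsize_deg=0.01)
        dem.elevation[:] = dem.nodata
        track = make_track([0], [-6.05], [37.35], [150.0])
        with pytest.raises(DemCoverageError):
            st.attach_agl(track, dem)

    def test_outside_extent_raises(self):
        track = make_track([0], [10.0], [37.35], [150.0])
        with pytest.raises(DemCoverageError):
            st.attach_agl(track, self.dem)

    def test_commutes_with_qc_when_not_dropping(self):
        track = make_track(np.arange(4), [-6.05] * 4, [37.35] * 4,
                           [150, 40, 150, 150], nsat=[8, 8, 3, 8],
                           dop=[1.0] * 4)
        a = st.attach_agl(st.qc_filter(track)[0], self.dem, drop_negative=False)[0]
        b = st.qc_filter(st.attach_agl(track, self.dem, drop_negative=False)[0])[0]
        pd.testing.assert_frame_equal(a.fixes, b.fixes)


class TestGeometry:
    def test_origin_is_zero(self):
        x, y = st.local_xy([-6.05], [37.35], -6.05, 37.35)
        assert x[0] == 0 and y[0] == 0

    def test_degree_north(self):
        _, y = st.local_xy([-6.05], [37.36], -6.05, 37.35)
        assert y[0] == pytest.approx(1111.95, abs=0.01)

    def test_degree_east_scales_with_latitude(self):
        x, _ = st.local_xy([-6.04], [37.0], -6.05, 37.0)
        assert x[0] == pytest.approx(1111.95 * np.cos(np.radians(37.0)), rel=1e-4)

    @given(dlon=hs.floats(-0.3, 0.3), dlat=hs.floats(-0.3, 0.3))
    def test_roundtrip(self, dlon, dlat):
        lon, lat = st.inverse_local_xy(
            *st.local_xy([-6.05 + dlon], [37.35 + dlat], -6.05, 37.35),
            -6.05, 37.35)
        assert lon[0] == pytest.approx(-6.05 + dlon, abs=1e-9)
        assert lat[0] == pytest.approx(37.35 + dlat, abs=1e-9)

    @given(dlon=hs.floats(-0.04, 0.04), dlat=hs.floats(-0.04, 0.04),
           lat0=hs.floats(-59.0, 59.0))
    def test_matches_haversine_under_5km(self, dlon, dlat, lat0):
        x, y = st.local_xy([-6.05 + dlon], [lat0 + dlat], -6.05, lat0)
        planar = float(np.hypot(x, y)[0])
        great = float(st.haversine_m(-6.05, lat0, -6.05 + dlon, lat0 + dlat))
        if great > 1.0:
            assert planar == pytest.approx(great, rel=1e-3)


class TestStepKinematics:
    def test_coincident_fixes(self):
        track = make_track([0, 1], [-6.05, -6.05], [37.35, 37.35], [80, 80])
        k = st.step_kinematics(track)
        assert k["distance_m"].iloc[0] == 0
        assert k["ground_speed_ms"].iloc[0] == 0

    def test_due_north_step(self):
        dlat = 10.0 / 111195.0  # ~10 m
        track = make_track([0, 1], [-6.05, -6.05], [37.35, 37.35 + dlat], [80, 80])
        k = st.step_kinematics(track)
        assert k["heading_deg"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert k["ground_speed_ms"].iloc[0] == pytest.approx(10.0, rel=1e-3)

    def test_climb_rate(self):
        track = make_track([0, 2], [-6.05, -6.05], [37.35, 37.35], [80, 83])
        track.fixes["agl"] = [100.0, 103.0]
        k = st.step_kinematics(track)
        assert k["climb_ms"].iloc[0] == pytest.approx(1.5)

    def test_non_increasing_time_rejected(self):
        fixes = pd.DataFrame({
            "timestamp": [pd.Timestamp("2012-06-15 10:00:00")] * 2,
            "lon": [-6.05] * 2, "lat": [37.35] * 2, "gps_altitude": [80.0] * 2,
        })
        with pytest.raises(ValueError):
            st.Track("bird", fixes, 1.0)


class TestRadiation:
    series = st.RadiationSeries(pd.Series(
        [500.0, 620.0],
        index=pd.to_datetime(["2012-06-15 10:00", "2012-06-15 10:30"])))

    @pytest.mark.parametrize("query,expected", [
        ("2012-06-15 10:07", 500.0),   # rounds down
        ("2012-06-15 10:16", 620.0),   # rounds up
        ("2012-06-15 10:15", 620.0),   # exact midpoint rounds up
        ("2012-06-15 10:44", 620.0),   # rounds down to :30
    ])
    def test_rounding(self, query, expected):
        assert st.radiation_at(self.series, query) == expected

    def test_missing_record(self):
        with pytest.raises(st.MissingWeatherError):
            self.series.at("2012-06-15 12:00")

    def test_csv_roundtrip(self, tmp_path):
        st.write_radiation(self.series, tmp_path / "rad.csv")
        back = st.read_radiation(tmp_path / "rad.csv")
        pd.testing.assert_series_equal(back.series, self.series.series,
                                       check_names=False)


class TestDem:
    def test_esri_roundtrip_exact(self, tmp_path):
        dem = st.make_dem(-6.1, -6.0, 37.3, 37.4, cellsize_deg=0.01,
                          base_elevation_m=50.0,
                          hills=[(-6.05, 37.35, 100.0, 0.02)])
        st.write_esri_ascii(dem, tmp_path / "dem.asc")
        back = st.read_esri_ascii(tmp_path / "dem.asc")
        np.testing.assert_array_equal(back.elevation, dem.elevation)
        assert back.cellsize == dem.cellsize
        assert back.xllcorner == dem.xllcorner

    def test_hill_lowers_agl(self):
        flat = st.make_dem(-6.1, -6.0, 37.3, 37.4, base_elevation_m=50.0)
        hilly = st.make_dem(-6.1, -6.0, 37.3, 37.4, base_elevation_m=50.0,
                            hills=[(-6.05, 37.35, 100.0, 0.05)])
        z_flat = flat.elevation_at(-6.05, 37.35)
        z_hill = hilly.elevation_at(-6.05, 37.35)
        assert z_hill - z_flat == pytest.approx(100.0, rel=0.01)


class TestSolar:
    def test_seville_midsummer(self):
        # published sun times for Seville (~ -6.0 E, 37.4 N), 2012-06-15:
        # sunrise ≈ 04:57 UTC, sunset ≈ 19:47 UTC
        rise, sett = st.sunrise_sunset("2012-06-15", -6.0, 37.4)
        assert abs((rise - pd.Timestamp("2012-06-15 04:57")).total_seconds()) < 600
        assert abs((sett - pd.Timestamp("2012-06-15 19:47")).total_seconds()) < 600

    def test_ordering(self):
        rise, sett = st.sunrise_sunset("2012-01-15", -6.0, 37.4)
        assert rise < sett
        assert rise.date().isoformat() == "2012-01-15"
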