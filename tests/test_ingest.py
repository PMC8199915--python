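"""File dialects, record validation, speed derivation, trip segmentation."""

import io
import textwrap

import numpy as np
import pandas as pd
import pytest

from cyclepm import ingest
from cyclepm.projection import rd_to_wgs84

HEADER = "device_id,timestamp_iso8601,lat,lon,pm25_raw,rh,temp\n"


def write_csv(tmp_path, body, name="m.csv"):
    p = tmp_path / name
    p.write_text(HEADER + textwrap.dedent(body))
    return p


class TestReadMeasurements:
    def test_well_formed_row_has_no_flags(self, tmp_path):
        p = write_csv(tmp_path, "dev1,2020-01-01T10:00:00Z,52.1,5.1,8.5,55,12\n")
        df, rejects = ingest.read_measurements(p)
        assert len(df) == 1 and len(rejects) == 0
        assert df["qc_flags"].iloc[0] == ""
        assert df["pm25_raw"].iloc[0] == 8.5
        assert str(df["time"].iloc[0].tz) == "UTC"

    def test_row_without_gps_fix_flagged_and_kept_aside(self, tmp_path):
        p = write_csv(tmp_path, "dev1,2020-01-01T10:00:00Z,,,8.5,55,12\n")
        df, rejects = ingest.read_measurements(p)
        assert len(df) == 1 and len(rejects) == 0
        assert ingest.has_flag(df["qc_flags"], ingest.FLAG_NO_POSITION).iloc[0]
        # downstream stages skip it: no speed, no trip membership
        df = ingest.compute_speeds(df)
        df = ingest.segment_trips(df)
        assert np.isnan(df["speed"].iloc[0])
        assert df["trip_id"].iloc[0] == ""

    def test_negative_concentration_rejected_with_reason(self, tmp_path):
        p = write_csv(tmp_path, "dev1,2020-01-01T10:00:00Z,52.1,5.1,-3.0,55,12\n")
        df, rejects = ingest.read_measurements(p)
        assert len(df) == 0
        assert rejects["reason"].iloc[0] == "negative pm25_raw"

    def test_unparseable_timestamp_rejected(self, tmp_path):
        p = write_csv(tmp_path, "dev1,not-a-time,52.1,5.1,8.5,55,12\n")
        _, rejects = ingest.read_measurements(p)
        assert rejects["reason"].iloc[0] == "unparseable timestamp"

    def test_missing_column_raises_naming_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("device_id,timestamp_iso8601,lat,lon,rh,temp\n")
        with pytest.raises(ingest.FormatError, match="pm25_raw"):
            ingest.read_measurements(p)

    def test_roundtrip_is_lossless(self, tmp_path, small_campaign):
        from cyclepm.synthetic import write_campaign
        paths = write_campaign(small_campaign, tmp_path)
        df, _ = ingest.read_measurements(paths["measurements"])
        out = tmp_path / "again.csv"
        ingest.write_measurements(df, out)
        df2, _ = ingest.read_measurements(out)
        for col in ("device_id", "time", "lat", "lon", "pm25_raw", "rh", "temp"):
            pd.testing.assert_series_equal(df[col], df2[col])


class TestStations:
    def test_reads_and_validates(self, tmp_path, small_campaign):
        from cyclepm.synthetic import write_campaign
        paths = write_campaign(small_campaign, tmp_path)
        st = ingest.read_stations(paths["stations"])
        assert set(st.columns) == {"station_id", "lat", "lon", "hour", "pm25"}
        assert (st["pm25"] >= 0).all()

    def test_duplicate_station_hour_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("station_id,lat,lon,hour_start_iso8601,pm25\n"
                     "s1,52.0,5.0,2020-01-01T00:00:00Z,9.0\n"
                     "s1,52.0,5.0,2020-01-01T00:00:00Z,9.5\n")
        with pytest.raises(ingest.FormatError):
            ingest.read_stations(p)


class TestPointSpeed:
    @staticmethod
    def row(t, lat, lon):
        return {"time": pd.Timestamp(t, tz="UTC"), "lat": lat, "lon": lon}

    def test_stationary_pair_is_zero(self):
        a = self.row("2020-01-01T10:00:00", 52.1, 5.1)
        b = self.row("2020-01-01T10:00:10", 52.1, 5.1)
        assert ingest.point_speed(a, b) == 0.0

    def test_ten_kmh_is_2_8_metres_per_second(self):
        # a bike at 10 km/h covers ~2.8 m between 1-s fixes
        assert 10.0 / 3.6 == pytest.approx(2.8, abs=0.03)

    def test_known_displacement_gives_10_kmh(self):
        # 27.78 m in 10 s = 10 km/h; construct coordinates via the
        # projection as an independent oracle for the haversine speed
        lat1, lon1 = rd_to_wgs84(140_000.0, 450_000.0)
        lat2, lon2 = rd_to_wgs84(140_000.0, 450_027.78)
        a = self.row("2020-01-01T10:00:00", float(lat1), float(lon1))
        b = self.row("2020-01-01T10:00:10", float(lat2), float(lon2))
        assert ingest.point_speed(a, b) == pytest.approx(10.0, abs=0.1)

    def test_zero_dt_is_undefined(self):
        a = self.row("2020-01-01T10:00:00", 52.1, 5.1)
        with pytest.raises(ValueError):
            ingest.point_speed(a, a)

    def test_first_point_inherits_successor_speed(self):
        df = pd.DataFrame({
            "device_id": ["d", "d", "d"],
            "time": pd.to_datetime(["2020-01-01T10:00:00Z",
                                    "2020-01-01T10:00:10Z",
                                    "2020-01-01T10:00:20Z"]),
            "lat": [52.0, 52.0001, 52.0002],
            "lon": [5.0, 5.0, 5.0],
            "qc_flags": "",
        })
        out = ingest.compute_speeds(df)
        assert out["speed"].iloc[0] == pytest.approx(out["speed"].iloc[1])


class TestSegmentTrips:
    @staticmethod
    def stream(n, start="2020-01-01T10:00:00Z", step_s=10, device="d"):
        t = pd.date_range(start, periods=n, freq=f"{step_s}s", tz="UTC")
        return pd.DataFrame({"device_id": device, "time": t,
                             "lat": 52.0, "lon": 5.0, "qc_flags": ""})

    def test_contiguous_stream_is_one_trip(self):
        out = ingest.segment_trips(self.stream(100))
        assert out["trip_id"].nunique() == 1
        assert (out.groupby("trip_id").size() == 100).all()

    def test_long_gap_splits_into_two_trips(self):
        a = self.stream(30)
        b = self.stream(30, start="2020-01-01T12:00:00Z")
        out = ingest.segment_trips(pd.concat([a, b], ignore_index=True))
        assert out["trip_id"].nunique() == 2

    def test_gap_at_threshold_does_not_split(self):
        a = self.stream(5)
        b = self.stream(5, start="2020-01-01T10:02:40Z")  # gap = 120 s
        out = ingest.segment_trips(pd.concat([a, b], ignore_index=True))
        assert out["trip_id"].nunique() == 1

    def test_single_record_is_single_point_trip(self):
        out = ingest.segment_trips(self.stream(1))
        assert out["trip_id"].nunique() == 1

    def test_partition_property(self, small_campaign):
        from cyclepm import pipeline
        df = pipeline.prepare(small_campaign.measurements)
        out = ingest.segment_trips(df)
        positioned = ~ingest.has_flag(out["qc_flags"], ingest.FLAG_NO_POSITION)
        assert (out.loc[positioned, "trip_id"] != "").all()
        assert out.loc[positioned].groupby("trip_id").size().sum() == positioned.sum()
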