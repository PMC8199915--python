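"""Hourly correction factor, guard rails, metrics and LSO validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclepm import calibration as cal
from cyclepm import pipeline
from cyclepm.synthetic import CampaignConfig, generate_campaign


def pairs(*rows):
    """(c_lml, c_sens[, n_values]) rows -> pairs frame for one hour."""
    out = []
    for r in rows:
        c_lml, c_sens = r[0], r[1]
        n = r[2] if len(r) > 2 else 1
        out.append({"c_lml": c_lml, "c_sens": c_sens, "n_values": n})
    return pd.DataFrame(out)


class TestHourlyBeta:
    def test_symmetric_ratios_average_to_one(self):
        hb = cal.hourly_beta(pairs((10.0, 8.0), (6.0, 8.0)))
        assert hb.beta == pytest.approx(1.0)
        assert hb.guard == "applied"
        assert hb.n_stations == 2

    def test_single_station_falls_back_to_unity(self):
        hb = cal.hourly_beta(pairs((10.4, 8.0)))
        assert hb.beta == 1.0
        assert hb.guard == "too_few_stations"

    def test_large_ratios_clamped_high(self):
        hb = cal.hourly_beta(pairs((48.0, 8.0), (48.0, 8.0)))
        assert hb.beta == 5.0
        assert hb.guard == "clamped_high"

    def test_small_ratios_clamped_low(self):
        hb = cal.hourly_beta(pairs((1.0, 10.0), (1.0, 10.0)))
        assert hb.beta == 0.5
        assert hb.guard == "clamped_low"

    def test_high_concentration_spread_disables_correction(self):
        # pooled sensors 20 > 15 and official SD 4 >= 0.15 * 20
        hb = cal.hourly_beta(pairs((24.0, 20.0), (16.0, 20.0)))
        assert hb.sigma_lml == pytest.approx(np.sqrt(32.0))
        assert hb.beta == 1.0
        assert hb.guard == "high_conc_unstable"

    def test_high_concentration_tight_spread_keeps_correction(self):
        hb = cal.hourly_beta(pairs((20.5, 20.0), (19.5, 20.0)))
        assert hb.guard == "applied"
        assert hb.beta == pytest.approx(1.0)

    def test_zero_sensor_mean_skipped_and_n_decremented(self):
        hb = cal.hourly_beta(pairs((10.0, 0.0), (9.0, 9.0)))
        assert hb.n_stations == 1
        assert hb.guard == "too_few_stations"

    @given(st.lists(st.tuples(st.floats(1.0, 30.0), st.floats(1.0, 30.0)),
                    min_size=1, max_size=5),
           st.floats(0.2, 5.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_equivariance_within_guards(self, rows, k):
        """Multiplying all sensor values by k divides beta by k, so the
        calibrated product is unchanged (when no guard interferes)."""
        base = cal.hourly_beta(pairs(*rows))
        scaled = cal.hourly_beta(pairs(*[(a, b * k) for a, b in rows]))
        if base.guard == "applied" and scaled.guard == "applied":
            assert scaled.beta * k == pytest.approx(base.beta, rel=1e-9)


class TestComparisonMetrics:
    def test_identical_series_all_zero(self):
        m = cal.comparison_metrics([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert m["bias"] == m["mae"] == m["rmse"] == m["ci95"] == 0.0

    def test_ci95_is_twice_sd_of_differences(self):
        # construct paired series whose differences have sample SD 1.1
        diffs = np.array([0.0, 1.1 * np.sqrt(2.0)])
        m = cal.comparison_metrics(10.0 + diffs, [10.0, 10.0])
        assert m["sd_diff"] == pytest.approx(1.1)
        assert m["ci95"] == pytest.approx(2.2)

    def test_hand_computed_example(self):
        m = cal.comparison_metrics([0.0, 2.0], [1.0, 1.0])
        assert m["bias"] == 0.0
        assert m["mae"] == 1.0
        assert m["rmse"] == 1.0

    def test_constant_series_has_undefined_pearson(self):
        m = cal.comparison_metrics([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        assert np.isnan(m["pearson"])

    @given(st.lists(st.tuples(st.floats(0, 30), st.floats(0, 30)),
                    min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mae_never_exceeds_rmse(self, rows):
        a, b = zip(*rows)
        m = cal.comparison_metrics(list(a), list(b))
        assert m["mae"] <= m["rmse"] + 1e-12


class TestStationSensorMeans:
    @staticmethod
    def measurements(n, value, lat, lon, start="2020-01-01T10:00:00Z"):
        t = pd.date_range(start, periods=n, freq="10s", tz="UTC")
        return pd.DataFrame({"device_id": "d", "time": t, "lat": lat,
                             "lon": lon, "pm25_raw": value})

    def test_colocated_hourly_mean(self):
        meta = pd.DataFrame({"station_id": ["s"], "lat": [52.1], "lon": [5.1]})
        m = self.measurements(360, 8.0, 52.1, 5.1)
        out = cal.station_sensor_means(m, meta)
        assert len(out) == 1
        assert out["c_sens"].iloc[0] == pytest.approx(8.0)

    def test_below_min_count_absent(self):
        meta = pd.DataFrame({"station_id": ["s"], "lat": [52.1], "lon": [5.1]})
        out = cal.station_sensor_means(self.measurements(5, 8.0, 52.1, 5.1),
                                       meta, min_count=6)
        assert len(out) == 0

    def test_pooling_over_individual_values(self):
        meta = pd.DataFrame({"station_id": ["s"], "lat": [52.1], "lon": [5.1]})
        close = self.measurements(10, 8.0, 52.1, 5.1)
        passing = self.measurements(10, 10.0, 52.105, 5.1)  # ~550 m away
        passing["device_id"] = "e"
        out = cal.station_sensor_means(pd.concat([close, passing]), meta)
        assert out["c_sens"].iloc[0] == pytest.approx(9.0)
        assert out["n_values"].iloc[0] == 20

    def test_far_sensor_ignored(self):
        meta = pd.DataFrame({"station_id": ["s"], "lat": [52.1], "lon": [5.1]})
        far = self.measurements(60, 8.0, 52.2, 5.1)  # ~11 km away
        assert len(cal.station_sensor_means(far, meta)) == 0


class TestApplyCalibration:
    def test_beta_scales_raw(self):
        t = pd.date_range("2020-01-01T10:00:00Z", periods=2, freq="10s")
        df = pd.DataFrame({"device_id": "d", "time": t, "pm25_raw": [10.0, 20.0],
                           "qc_flags": ""})
        betas = pd.DataFrame({"hour": [t.floor("h")[0]], "beta": [1.2]})
        out = cal.apply_calibration(df, betas)
        assert out["pm25_cal"].tolist() == [12.0, 24.0]
        assert (out["qc_flags"] == "").all()

    def test_uncovered_hour_falls_back_flagged(self):
        t = pd.date_range("2020-01-01T10:00:00Z", periods=1, freq="10s")
        df = pd.DataFrame({"device_id": "d", "time": t, "pm25_raw": [10.0],
                           "qc_flags": ""})
        out = cal.apply_calibration(df, pd.DataFrame(columns=["hour", "beta"]))
        assert out["pm25_cal"].iloc[0] == 10.0
        assert out["qc_flags"].iloc[0] == "UNCALIBRATED_HOUR"


class TestLSO:
    def test_perfect_sensors_validate_perfectly(self):
        # gain-1, noise-free campaign: LSO errors vanish
        cfg = CampaignConfig(seed=2, n_devices=2, n_days=3, traffic_peak=0.0,
                             noise_sd_10s=0.0, device_gain_sd=0.0,
                             rh_gain_slope=0.0, station_noise_sd=0.0,
                             background_sigma_log=0.0,
                             frac_flatlow_devices=0.0, frac_highbias_devices=0.0)
        camp = generate_campaign(cfg)
        df = pipeline.prepare(camp.measurements)
        rep = cal.lso_validate(df, camp.stations)
        avg = rep.loc["average"]
        assert avg["mae_lso"] == pytest.approx(0.0, abs=1e-3)
        assert avg["rmse_lso"] == pytest.approx(0.0, abs=1e-3)

    def test_single_station_campaign_rejected(self):
        cfg = CampaignConfig(seed=2, n_devices=2, n_days=2,
                             station_locations=((4400.0, 4400.0),))
        camp = generate_campaign(cfg)
        df = pipeline.prepare(camp.measurements)
        with pytest.raises(ValueError):
            cal.lso_validate(df, camp.stations)

    def test_common_gain_bias_removed(self):
        # all sensors read 15% low; the ratio calibration restores the level
        cfg = CampaignConfig(seed=4, n_devices=6, n_days=5,
                             device_gain_mean=0.85, device_gain_sd=0.0,
                             frac_flatlow_devices=0.0, frac_highbias_devices=0.0)
        camp = generate_campaign(cfg)
        df = pipeline.prepare(camp.measurements)
        rep = cal.lso_validate(df, camp.stations)
        avg = rep.loc["average"]
        assert avg["bias_raw"] < -1.0
        assert abs(avg["bias_lso"]) < 0.3
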