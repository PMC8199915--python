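"""Shared fixtures: small synthetic campaigns, generated once per session."""

import pandas as pd
import pytest

import cyclepm
from cyclepm.synthetic import CampaignConfig, generate_campaign


@pytest.fixture(scope="session")
def small_campaign():
    """A small default-conditions campaign for generic pipeline tests."""
    return generate_campaign(CampaignConfig(seed=11, n_devices=10, n_days=7))


@pytest.fixture(scope="session")
def small_result(small_campaign):
    return cyclepm.run(small_campaign.measurements, small_campaign.stations)


@pytest.fixture(scope="session")
def default_campaign():
    """Full default study conditions (20 devices, 30 days), seed fixed."""
    return generate_campaign(CampaignConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_campaign):
    return cyclepm.run(default_campaign.measurements, default_campaign.stations)


def make_measurements(rows):
    """Build a normalized measurement frame from (device, iso_time, lat, lon,
    pm25, speed) tuples, bypassing file I/O."""
    df = pd.DataFrame(rows, columns=["device_id", "time", "lat", "lon",
                                     "pm25_raw", "speed"])
    df["time"] = pd.to_datetime(df["time"], utc=True)
    df["rh"] = 50.0
    df["temp"] = 10.0
    df["pm25_cal"] = float("nan")
    df["qc_flags"] = ""
    df.index.name = "point_id"
    return df
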