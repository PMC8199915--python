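"""Hourly ratio calibration of mobile sensors against reference stations.

Low-cost optical PM sensors carry multiplicative biases (device gain,
humidity response).  Because the study region is small and fairly uniform,
a single hourly correction factor

    beta(h) = (1/n) * sum_s C_official(s, h) / C_sensors(s, h)

is estimated over the n reference stations s that have both an official
hourly value and enough co-located or passing sensor data in hour h, and is
applied multiplicatively to every mobile record in that hour.  Guard rails
keep the correction conservative: beta = 1 when fewer than two stations
contribute, beta is clamped into [0.5, 5.0], and at high concentrations
(pooled sensor mean > 15 ug/m3) the correction is only applied when the
official values agree well across stations (sigma < 0.15 x mean), since a
large spread means one area-wide factor is not representative.

Validation is by Leave-Station-Out (LSO): the factors are recomputed
without one station's official data and judged against that station.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import FLAG_UNCALIBRATED_HOUR, add_flag
from .projection import haversine_m

__all__ = [
    "BETA_MIN",
    "BETA_MAX",
    "HourlyBeta",
    "station_sensor_means",
    "hourly_beta",
    "hourly_beta_table",
    "apply_calibration",
    "comparison_metrics",
    "lso_validate",
]

BETA_MIN = 0.5
BETA_MAX = 5.0
HIGH_CONC = 15.0        # ug/m3, pooled sensor mean triggering the guard
SIGMA_FRAC = 0.15       # relative official spread allowed at high conc.


@dataclass(frozen=True)
class HourlyBeta:
    """One hour's correction factor with its provenance."""
    hour: object
    beta: float
    n_stations: int
    mean_lml: float      # mean official value over contributing stations
    sigma_lml: float     # sample SD of official values over stations
    mean_sensors: float  # pooled mean over all contributing sensor values
    guard: str           # applied | too_few_stations | clamped_low |
                         # clamped_high | high_conc_unstable


def station_sensor_means(measurements: pd.DataFrame, stations_meta: pd.DataFrame,
                         radius: float = 1000.0,
                         min_count: int = 6) -> pd.DataFrame:
    """Hourly sensor mean near each station.

    For every station and hour, the mean and count of all sensor values
    (co-located kits and passing bikes alike) recorded within ``radius``
    metres of the station; station-hours with fewer than ``min_count``
    values are absent from the result.  A sensor inside two stations'
    radii contributes to both.
    """
    metas = stations_meta.drop_duplicates("station_id")
    hours = measurements["time"].dt.floor("h")
    rows = []
    lat = measurements["lat"].to_numpy()
    lon = measurements["lon"].to_numpy()
    for _, st in metas.iterrows():
        d = haversine_m(lat, lon, st["lat"], st["lon"])
        near = d <= radius
        if not near.any():
            continue
        grp = measurements.loc[near].groupby(hours[near])["pm25_raw"]
        agg = grp.agg(["mean", "count"])
        agg = agg[agg["count"] >= min_count]
        for hour, row in agg.iterrows():
            rows.append({"station_id": st["station_id"], "hour": hour,
                         "c_sens": row["mean"], "n_values": int(row["count"])})
    if not rows:
        return pd.DataFrame(columns=["station_id", "hour", "c_sens", "n_values"])
    return pd.DataFrame(rows)


def hourly_beta(pairs: pd.DataFrame, hour=None) -> HourlyBeta:
    """Correction factor for one hour from per-station (official, sensor) pairs.

    ``pairs`` needs columns ``c_lml``, ``c_sens`` and optionally
    ``n_values`` (sensor value count behind each mean, default 1, used for
    the pooled sensor mean).  Stations with ``c_sens`` = 0 are skipped and
    do not count towards n.  Guards are applied sequentially: n < 2
    override, clamp into [0.5, 5.0], then the high-concentration stability
    override.
    """
    p = pairs.loc[pairs["c_sens"] > 0]
    n = len(p)
    if n == 0:
        return HourlyBeta(hour, 1.0, 0, np.nan, np.nan, np.nan,
                          "too_few_stations")
    nv = p["n_values"].to_numpy(float) if "n_values" in p.columns else \
        np.ones(n)
    mean_lml = float(p["c_lml"].mean())
    sigma_lml = float(p["c_lml"].std(ddof=1)) if n > 1 else np.nan
    mean_sensors = float(np.sum(p["c_sens"].to_numpy() * nv) / np.sum(nv))
    beta = float((p["c_lml"] / p["c_sens"]).mean())
    guard = "applied"
    if n < 2:
        return HourlyBeta(hour, 1.0, n, mean_lml, sigma_lml, mean_sensors,
                          "too_few_stations")
    if beta < BETA_MIN:
        beta, guard = BETA_MIN, "clamped_low"
    elif beta > BETA_MAX:
        beta, guard = BETA_MAX, "clamped_high"
    if mean_sensors > HIGH_CONC and sigma_lml >= SIGMA_FRAC * mean_lml:
        return HourlyBeta(hour, 1.0, n, mean_lml, sigma_lml, mean_sensors,
                          "high_conc_unstable")
    return HourlyBeta(hour, beta, n, mean_lml, sigma_lml, mean_sensors, guard)


def hourly_beta_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Correction factors for every hour present in the pairs table.

    ``pairs`` has one row per (station, hour) with ``c_lml``, ``c_sens``
    and ``n_values``.  Returns one row per hour in HourlyBeta layout.
    """
    rows = [hourly_beta(grp, hour) for hour, grp in pairs.groupby("hour")]
    if not rows:
        return pd.DataFrame(columns=["hour", "beta", "n_stations", "mean_lml",
                                     "sigma_lml", "mean_sensors", "guard"])
    return pd.DataFrame([vars(r) for r in rows])


def build_pairs(measurements: pd.DataFrame, stations: pd.DataFrame,
                radius: float = 1000.0, min_count: int = 6) -> pd.DataFrame:
    """Join per-station-hour sensor means with official hourly values."""
    meta = stations[["station_id", "lat", "lon"]]
    sens = station_sensor_means(measurements, meta, radius, min_count)
    off = stations[["station_id", "hour", "pm25"]].rename(columns={"pm25": "c_lml"})
    return sens.merge(off, on=["station_id", "hour"], how="inner")


def apply_calibration(measurements: pd.DataFrame,
                      betas: pd.DataFrame) -> pd.DataFrame:
    """Multiply each record by its hour's beta to fill ``pm25_cal``.

    Hours without a correction factor fall back to beta = 1 and are flagged
    ``UNCALIBRATED_HOUR`` so sensitivity analyses can find them.
    """
    df = measurements.copy()
    lut = betas.set_index("hour")["beta"] if len(betas) else pd.Series(dtype=float)
    hours = df["time"].dt.floor("h")
    b = lut.reindex(hours).to_numpy()
    missing = np.isnan(b)
    b[missing] = 1.0
    df["pm25_cal"] = df["pm25_raw"] * b
    df["qc_flags"] = add_flag(df["qc_flags"], pd.Series(missing, index=df.index),
                              FLAG_UNCALIBRATED_HOUR)
    return df


def comparison_metrics(sensor: np.ndarray | pd.Series,
                       official: np.ndarray | pd.Series) -> dict:
    """Agreement metrics between paired hourly series.

    bias = mean(sensor - official); MAE; RMSE; Pearson correlation (NaN for
    constant series, where it is undefined); sd_diff is the sample standard
    deviation of the differences and ci95 = 2 * sd_diff, the convention
    used for sensor-vs-reference uncertainty statements.
    """
    a = np.asarray(sensor, dtype=float)
    b = np.asarray(official, dtype=float)
    if len(a) < 2 or len(a) != len(b):
        raise ValueError("need at least two paired values")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        pearson = np.nan
    else:
        pearson = float(np.corrcoef(a, b)[0, 1])
    return {
        "mean_sensor": float(a.mean()),
        "mean_official": float(b.mean()),
        "bias": float(d.mean()),
        "mae": float(np.abs(d).mean()),
        "rmse": float(np.sqrt(np.mean(d**2))),
        "pearson": pearson,
        "sd_diff": sd,
        "ci95": 2.0 * sd,
    }


def lso_validate(measurements: pd.DataFrame, stations: pd.DataFrame,
                 radius: float = 1000.0, min_count: int = 6,
                 min_pairs: int = 24) -> pd.DataFrame:
    """Leave-Station-Out validation of the hourly calibration.

    For every station with at least ``min_pairs`` paired hours, the hourly
    factors are recomputed excluding that station's official data and
    applied to the sensor series at the station; raw and LSO-calibrated
    values are then compared with the official series.  The returned frame
    has one row per station plus an ``average`` row of column means.
    """
    pairs = build_pairs(measurements, stations, radius, min_count)
    usable = [s for s, g in pairs.groupby("station_id") if len(g) >= min_pairs]
    if len(usable) < 2:
        raise ValueError("LSO validation needs at least two stations with "
                         "co-located sensor data")
    rows = []
    for sid in usable:
        own = pairs.loc[pairs["station_id"] == sid].set_index("hour")
        others = pairs.loc[pairs["station_id"] != sid]
        betas = hourly_beta_table(others).set_index("hour")["beta"]
        b = betas.reindex(own.index).fillna(1.0)
        raw = own["c_sens"]
        lso = raw * b
        official = own["c_lml"]
        m_raw = comparison_metrics(raw, official)
        m_lso = comparison_metrics(lso, official)
        rows.append({
            "station_id": sid,
            "n_hours": len(own),
            "mean_official": m_raw["mean_official"],
            "mean_raw": m_raw["mean_sensor"],
            "mean_lso": m_lso["mean_sensor"],
            "pearson_raw": m_raw["pearson"],
            "pearson_lso": m_lso["pearson"],
            "mae_raw": m_raw["mae"],
            "mae_lso": m_lso["mae"],
            "rmse_raw": m_raw["rmse"],
            "rmse_lso": m_lso["rmse"],
            "bias_raw": m_raw["bias"],
            "bias_lso": m_lso["bias"],
        })
    report = pd.DataFrame(rows).set_index("station_id")
    avg = report.mean(numeric_only=True)
    report.loc["average"] = avg
    return report
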