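"""Validity filters for mobile sensor records.

Four rules, applied in a fixed order: (1) a speed window that removes
stationary/indoor use and motorised transport, (2) device-level screening
of flat-low and high-biased kits against the regional reference mean over
each device's active hours, (3) trimming of the first and last 5% of each
trip (sensor warm-up after indoor-outdoor transfer), and (4) a minimum
point count per trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import FLAG_DEVICE_SUSPECT, FLAG_SPEED, add_flag, has_flag

__all__ = [
    "QCParams",
    "speed_filter",
    "device_summaries",
    "screen_devices",
    "trim_trips",
    "min_points_filter",
    "apply_qc",
]


@dataclass(frozen=True)
class QCParams:
    v_min: float = 5.0        # km/h, inclusive lower bound
    v_max: float = 45.0       # km/h, inclusive upper bound
    low_mean: float = 3.0     # ug/m3, flat-low device threshold
    high_ratio: float = 3.0   # x regional mean, high-outlier threshold
    trim_frac: float = 0.05   # fraction trimmed off each trip end
    min_points: int = 25      # minimum points per trip after trimming


def flag_speed_violations(df: pd.DataFrame, v_min: float = 5.0,
                          v_max: float = 45.0) -> pd.DataFrame:
    """Add the ``SPEED`` flag to points outside [v_min, v_max] km/h."""
    df = df.copy()
    df["qc_flags"] = add_flag(df["qc_flags"], ~speed_mask(df, v_min, v_max),
                              FLAG_SPEED)
    return df


def speed_filter(df: pd.DataFrame, v_min: float = 5.0,
                 v_max: float = 45.0) -> pd.DataFrame:
    """Keep points with v_min <= speed <= v_max (bounds inclusive)."""
    return df.loc[speed_mask(df, v_min, v_max)].copy()


def speed_mask(df: pd.DataFrame, v_min: float = 5.0,
               v_max: float = 45.0) -> pd.Series:
    s = df["speed"]
    return s.notna() & (s >= v_min) & (s <= v_max)


def regional_hourly_mean(stations: pd.DataFrame) -> pd.Series:
    """Across-station mean official concentration per hour."""
    return stations.groupby("hour")["pm25"].mean()


def device_summaries(valid: pd.DataFrame, stations: pd.DataFrame) -> pd.DataFrame:
    """Per-device mean vs the regional reference mean over active hours.

    ``valid`` should already be speed-filtered; the regional match uses the
    across-station mean of official values during the hours in which the
    device reported valid data.
    """
    regional = regional_hourly_mean(stations)
    out = []
    hours = valid["time"].dt.floor("h")
    for device, grp in valid.groupby("device_id", sort=True):
        active = hours.loc[grp.index].unique()
        matched = regional.reindex(active).dropna()
        out.append({
            "device_id": device,
            "n_valid": len(grp),
            "mean_pm25": grp["pm25_raw"].mean(),
            "matched_regional_mean": matched.mean() if len(matched) else np.nan,
        })
    return pd.DataFrame(out).set_index("device_id")


def screen_devices(summaries: pd.DataFrame, low_mean: float = 3.0,
                   high_ratio: float = 3.0) -> pd.DataFrame:
    """Exclusion decision per device.

    flat_low: campaign mean below ``low_mean`` ug/m3.  high_outlier:
    campaign mean above ``high_ratio`` times the matched regional mean.
    Devices with no valid points are excluded with reason ``empty``.
    """
    res = summaries.copy()
    reason = pd.Series("none", index=res.index, dtype=object)
    empty = res["n_valid"] == 0
    reason[empty] = "empty"
    flat = ~empty & (res["mean_pm25"] < low_mean)
    reason[flat] = "flat_low"
    high = (~empty & ~flat & res["matched_regional_mean"].notna() &
            (res["mean_pm25"] > high_ratio * res["matched_regional_mean"]))
    reason[high] = "high_outlier"
    res["exclusion_reason"] = reason
    return res


def trim_trips(df: pd.DataFrame, frac: float = 0.05) -> pd.DataFrame:
    """Drop the first and last floor(frac*n) points of every trip."""
    if df.empty:
        return df.copy()
    grp = df.groupby("trip_id", sort=False)
    n = grp["trip_id"].transform("size")
    k = np.floor(frac * n).astype(int)
    pos = grp.cumcount()
    keep = (pos >= k) & (pos < n - k)
    return df.loc[keep].copy()


def min_points_filter(df: pd.DataFrame, min_n: int = 25) -> pd.DataFrame:
    """Keep only trips with at least ``min_n`` points."""
    if df.empty:
        return df.copy()
    sizes = df.groupby("trip_id")["trip_id"].transform("size")
    return df.loc[sizes >= min_n].copy()


def apply_qc(df: pd.DataFrame, stations: pd.DataFrame,
             params: QCParams = QCParams()) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full QC chain: speed -> device screening -> trim -> min points.

    ``df`` must carry speeds and trip ids.  Returns ``(clean, summaries,
    report)`` where ``clean`` is the exposure-ready point set, ``summaries``
    the per-device screening table and ``report`` counts removed per rule.
    Device means are computed on speed-valid points only.
    """
    report = {"n_input": len(df)}
    valid = df.loc[speed_mask(df, params.v_min, params.v_max)].copy()
    report["removed_speed"] = report["n_input"] - len(valid)

    all_devices = pd.Index(df["device_id"].unique(), name="device_id")
    summaries = device_summaries(valid, stations).reindex(all_devices)
    summaries["n_valid"] = summaries["n_valid"].fillna(0).astype(int)
    summaries = screen_devices(summaries, params.low_mean, params.high_ratio)

    bad = summaries.index[summaries["exclusion_reason"].isin(
        ["flat_low", "high_outlier"])]
    suspect = valid["device_id"].isin(bad)
    valid["qc_flags"] = add_flag(valid["qc_flags"], suspect, FLAG_DEVICE_SUSPECT)
    kept = valid.loc[~suspect]
    report["removed_device_screen"] = len(valid) - len(kept)

    trimmed = trim_trips(kept, params.trim_frac)
    report["removed_trim"] = len(kept) - len(trimmed)
    final = min_points_filter(trimmed, params.min_points)
    report["removed_min_points"] = len(trimmed) - len(final)
    report["n_retained"] = len(final)
    return final, summaries, report
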