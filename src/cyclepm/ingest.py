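"""Reading and normalising raw mobile measurements and station series.

The measurement dialect is a comma-separated UTF-8 file with header
``device_id,timestamp_iso8601,lat,lon,pm25_raw,rh,temp``; stations use
``station_id,lat,lon,hour_start_iso8601,pm25``.  Malformed rows are not
fatal: they are collected in a rejects report with a reason, mirroring how
an operational pipeline keeps an audit trail of discarded telemetry.
Records without a GPS fix are retained but flagged ``NO_POSITION``; every
downstream stage ignores them, since neither location nor speed can be
derived for them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .projection import haversine_m

__all__ = [
    "FormatError",
    "read_measurements",
    "write_measurements",
    "read_stations",
    "compute_speeds",
    "segment_trips",
    "FLAG_NO_POSITION",
    "FLAG_SPEED",
    "FLAG_DEVICE_SUSPECT",
    "FLAG_UNCALIBRATED_HOUR",
]

FLAG_NO_POSITION = "NO_POSITION"
FLAG_SPEED = "SPEED"
FLAG_DEVICE_SUSPECT = "DEVICE_SUSPECT"
FLAG_UNCALIBRATED_HOUR = "UNCALIBRATED_HOUR"

_MEAS_COLS = ["device_id", "timestamp_iso8601", "lat", "lon", "pm25_raw", "rh", "temp"]
_STATION_COLS = ["station_id", "lat", "lon", "hour_start_iso8601", "pm25"]


class FormatError(ValueError):
    """Raised when a file does not match the expected dialect."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} file is missing column(s): {', '.join(missing)}")


def add_flag(flags: pd.Series, mask, flag: str) -> pd.Series:
    """Append ``flag`` to the pipe-separated flag strings where ``mask``."""
    flags = flags.copy()
    has = flags.str.contains(flag, regex=False)
    tgt = mask & ~has
    flags.loc[tgt] = np.where(flags.loc[tgt] == "", flag,
                              flags.loc[tgt] + "|" + flag)
    return flags


def has_flag(flags: pd.Series, flag: str) -> pd.Series:
    return flags.str.contains(flag, regex=False)


def read_measurements(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a measurement CSV.

    Returns ``(measurements, rejects)``.  Measurements carry parsed UTC
    times, a float schema and an empty-string ``qc_flags`` column; rows
    without a GPS fix get the ``NO_POSITION`` flag.  Rows violating hard
    invariants (bad timestamp, negative concentration, out-of-range
    coordinates) land in the rejects frame with a ``reason`` column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, _MEAS_COLS, "measurement")

    time = pd.to_datetime(raw["timestamp_iso8601"], errors="coerce",
                          utc=True, format="ISO8601")
    pm = pd.to_numeric(raw["pm25_raw"], errors="coerce")
    lat = pd.to_numeric(raw["lat"], errors="coerce")
    lon = pd.to_numeric(raw["lon"], errors="coerce")
    rh = pd.to_numeric(raw["rh"], errors="coerce")
    temp = pd.to_numeric(raw["temp"], errors="coerce")

    reason = pd.Series("", index=raw.index, dtype=object)
    reason[time.isna()] = "unparseable timestamp"
    reason[(reason == "") & pm.isna()] = "unparseable pm25_raw"
    reason[(reason == "") & (pm < 0)] = "negative pm25_raw"
    bad_coord = (lat.notna() & ((lat < -90) | (lat > 90))) | \
                (lon.notna() & ((lon < -180) | (lon > 180)))
    reason[(reason == "") & bad_coord] = "coordinate out of range"
    reason[(reason == "") & (raw["device_id"].str.strip() == "")] = "empty device_id"

    rejected = reason != ""
    rejects = raw.loc[rejected].copy()
    rejects["reason"] = reason[rejected]

    ok = ~rejected
    df = pd.DataFrame({
        "device_id": raw.loc[ok, "device_id"],
        "time": time[ok],
        "lat": lat[ok],
        "lon": lon[ok],
        "pm25_raw": pm[ok],
        "rh": rh[ok],
        "temp": temp[ok],
    })
    df["pm25_cal"] = np.nan
    df["speed"] = np.nan
    df["qc_flags"] = ""
    no_pos = df["lat"].isna() | df["lon"].isna()
    df["qc_flags"] = add_flag(df["qc_flags"], no_pos, FLAG_NO_POSITION)
    df = df.sort_values(["device_id", "time"], kind="mergesort")
    df = df.reset_index(drop=True)
    df.index.name = "point_id"
    return df, rejects.reset_index(drop=True)


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    """Write measurements back to the CSV dialect (lossless round-trip)."""
    out = pd.DataFrame({
        "device_id": df["device_id"],
        "timestamp_iso8601": df["time"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
        "lat": df["lat"],
        "lon": df["lon"],
        "pm25_raw": df["pm25_raw"],
        "rh": df["rh"],
        "temp": df["temp"],
    })
    out.to_csv(path, index=False)


def read_stations(path: str | Path) -> pd.DataFrame:
    """Read the hourly reference-station CSV.

    Returns a frame with columns station_id, lat, lon, hour (UTC), pm25.
    Negative concentrations or duplicate station-hours violate the station
    contract and raise a FormatError.
    """
    raw = pd.read_csv(path)
    _require_columns(raw, _STATION_COLS, "station")
    df = pd.DataFrame({
        "station_id": raw["station_id"].astype(str),
        "lat": raw["lat"].astype(float),
        "lon": raw["lon"].astype(float),
        "hour": pd.to_datetime(raw["hour_start_iso8601"], utc=True, format="ISO8601"),
        "pm25": raw["pm25"].astype(float),
    })
    if (df["pm25"] < 0).any():
        raise FormatError("station series contains negative concentrations")
    if df.duplicated(["station_id", "hour"]).any():
        raise FormatError("station series has duplicate station-hour rows")
    return df


def point_speed(prev, cur) -> float:
    """Speed in km/h between two consecutive fixes of one device.

    ``prev`` and ``cur`` are mappings with ``time``, ``lat`` and ``lon``.
    Raises ValueError when the timestamps coincide (speed undefined).
    """
    dt = (cur["time"] - prev["time"]).total_seconds()
    if dt <= 0:
        raise ValueError("undefined speed: non-increasing timestamps")
    d = float(haversine_m(prev["lat"], prev["lon"], cur["lat"], cur["lon"]))
    return d / dt * 3.6


def compute_speeds(df: pd.DataFrame) -> pd.DataFrame:
    """Derive point speeds (km/h) from consecutive fixes of each device.

    The speed at a point is the great-circle distance from the previous fix
    of the same device divided by the elapsed time; the first point of a
    device stream inherits the speed of its successor segment.  Records
    flagged NO_POSITION are left untouched (speed stays NaN).
    """
    df = df.copy()
    pos = ~has_flag(df["qc_flags"], FLAG_NO_POSITION)
    sub = df.loc[pos]
    g = sub.groupby("device_id", sort=False)
    dt = g["time"].diff().dt.total_seconds()
    dmet = haversine_m(g["lat"].shift(), g["lon"].shift(), sub["lat"], sub["lon"])
    speed = pd.Series(dmet, index=sub.index) / dt * 3.6
    speed[dt == 0] = np.nan
    first = dt.isna()
    nxt = speed.groupby(sub["device_id"]).shift(-1)
    speed[first] = nxt[first]
    df.loc[pos, "speed"] = speed
    return df


def segment_trips(df: pd.DataFrame, gap_threshold: float = 120.0) -> pd.DataFrame:
    """Split each device's stream into trips at gaps > ``gap_threshold`` s.

    Adds a ``trip_id`` column (``<device>-t<k>``); NO_POSITION records get
    an empty trip id and are excluded from every trip.  Every positioned
    record belongs to exactly one trip.
    """
    df = df.copy()
    df["trip_id"] = ""
    pos = ~has_flag(df["qc_flags"], FLAG_NO_POSITION)
    sub = df.loc[pos]
    if sub.empty:
        return df
    dt = sub.groupby("device_id", sort=False)["time"].diff().dt.total_seconds()
    new_trip = dt.isna() | (dt > gap_threshold)
    trip_no = new_trip.groupby(sub["device_id"]).cumsum().astype(int) - 1
    ids = sub["device_id"] + "-t" + trip_no.map("{:04d}".format)
    df.loc[pos, "trip_id"] = ids
    return df
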