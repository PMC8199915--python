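"""End-to-end convenience driver: raw records -> trip increments -> grid.

Chains the stage modules in the canonical order: normalisation and speed
derivation, trip segmentation, QC (speed window, device screening,
trimming, minimum points), hourly ratio calibration, percentile background
subtraction, and grid aggregation.  Each stage remains individually usable;
this module only wires them together with one parameter object.

Calibration input deliberately differs from the exposure chain: the
stationary co-located kits that anchor the hourly factors fail the
5-45 km/h speed window by construction, so the factors are computed from
all position-valid records of devices that passed screening, while the
exposure analysis uses the fully speed-filtered trip points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import calibration, exposure, ingest, qc, spatial

__all__ = ["PipelineParams", "PipelineResult", "prepare", "run"]


@dataclass(frozen=True)
class PipelineParams:
    qc: qc.QCParams = field(default_factory=qc.QCParams)
    gap_threshold_s: float = 120.0
    radius_m: float = 1000.0
    min_count: int = 6
    percentile: float = 0.10
    stability_threshold: float = 2.5
    exclude_unstable: bool = False
    grid: spatial.GridSpec = field(default_factory=spatial.GridSpec)
    min_obs: int = 15
    min_devices: int = 3


@dataclass
class PipelineResult:
    clean: pd.DataFrame          # QC-passed, calibrated trip points
    summaries: pd.DataFrame      # per-device screening table
    qc_report: dict
    betas: pd.DataFrame          # hourly correction factors
    trips: pd.DataFrame          # per-trip exposure table
    points: pd.DataFrame         # per-point signed increments
    cells: pd.DataFrame          # grid-cell statistics
    unstable_hours: pd.Index


def prepare(measurements: pd.DataFrame) -> pd.DataFrame:
    """Bring an in-memory measurement frame to the normalized schema."""
    df = measurements.copy()
    for col, default in (("pm25_cal", pd.NA), ("speed", pd.NA), ("qc_flags", "")):
        if col not in df.columns:
            df[col] = default
    df["pm25_cal"] = pd.to_numeric(df["pm25_cal"], errors="coerce")
    df["speed"] = pd.to_numeric(df["speed"], errors="coerce")
    df = df.sort_values(["device_id", "time"], kind="mergesort").reset_index(drop=True)
    df.index.name = "point_id"
    return df


def run(measurements: pd.DataFrame, stations: pd.DataFrame,
        params: PipelineParams = PipelineParams()) -> PipelineResult:
    """Run the full analysis on normalized measurements and station series."""
    df = prepare(measurements)
    df = ingest.compute_speeds(df)
    df = ingest.segment_trips(df, params.gap_threshold_s)

    clean, summaries, report = qc.apply_qc(df, stations, params.qc)

    # calibration pool: position-valid records of non-suspect devices
    good_devices = summaries.index[~summaries["exclusion_reason"].isin(
        ["flat_low", "high_outlier"])]
    pos_ok = ~ingest.has_flag(df["qc_flags"], ingest.FLAG_NO_POSITION)
    pool = df.loc[pos_ok & df["device_id"].isin(good_devices)]
    pairs = calibration.build_pairs(pool, stations, params.radius_m,
                                    params.min_count)
    betas = calibration.hourly_beta_table(pairs)
    clean = calibration.apply_calibration(clean, betas)

    _, unstable = exposure.stable_hours(stations, params.stability_threshold)
    trips, points = exposure.trip_exposures(
        clean, percentile=params.percentile, min_points=params.qc.min_points,
        unstable_hours=unstable)
    if params.exclude_unstable and not trips.empty:
        keep = ~trips["excluded_unstable_hour"]
        trips = trips.loc[keep]
        points = points.loc[points["trip_id"].isin(trips.index)]

    cells = spatial.aggregate_cells(points, params.grid, params.min_obs,
                                    params.min_devices) if not points.empty \
        else pd.DataFrame()
    return PipelineResult(clean=clean, summaries=summaries, qc_report=report,
                          betas=betas, trips=trips, points=points,
                          cells=cells, unstable_hours=unstable)
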