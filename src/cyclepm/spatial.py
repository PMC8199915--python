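"""Metric-grid aggregation of point increments and the co-incidence diagnostic.

Point increments are projected onto a planar grid (25 m cells by default,
Dutch RD New metres) and averaged per cell.  Cells are only *reported* with
at least 15 observations from at least 3 distinct devices, protecting the
map from single-rider artefacts; reported cells are classified into five
quantile classes of equal share.  A separate 50 m same-hour co-incidence
diagnostic quantifies mobile sensor precision: when two or more devices
cross the same cell in the same hour, the spread of their per-device means
estimates between-sensor scatter under field conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .projection import rd_to_wgs84, wgs84_to_rd

__all__ = [
    "GridSpec",
    "project_point",
    "cell_index",
    "aggregate_cells",
    "quantile_classes",
    "coincidence_scatter",
    "cells_to_geojson",
]


@dataclass(frozen=True)
class GridSpec:
    """A planar analysis grid: origin (metres), cell size, projection."""
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 25.0
    projection: str = "EPSG:28992"

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.projection != "EPSG:28992":
            raise ValueError("only the EPSG:28992 planar grid is supported")


def cell_index(x, y, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Half-open cell indices for planar coordinates: [edge, edge + size)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    i = np.floor((x - grid.origin[0]) / grid.cell_size).astype(int)
    j = np.floor((y - grid.origin[1]) / grid.cell_size).astype(int)
    return i, j


def project_point(lat, lon, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Cell indices for WGS84 positions via the grid's planar projection."""
    x, y = wgs84_to_rd(lat, lon)
    return cell_index(x, y, grid)


def aggregate_cells(points: pd.DataFrame, grid: GridSpec,
                    min_obs: int = 15, min_devices: int = 3,
                    value_col: str = "increment") -> pd.DataFrame:
    """Per-cell statistics of point increments with suppression flags.

    ``points`` must carry ``lat``, ``lon``, ``device_id`` and the value
    column.  A cell is ``reported`` only when it holds at least ``min_obs``
    observations from at least ``min_devices`` distinct devices; reported
    cells additionally get a 1..5 ``quantile_class``.
    """
    if points.empty:
        return pd.DataFrame(columns=["i", "j", "n_obs", "n_devices",
                                     "mean_increment", "reported",
                                     "quantile_class"])
    i, j = project_point(points["lat"].to_numpy(), points["lon"].to_numpy(), grid)
    df = pd.DataFrame({"i": i, "j": j,
                       "device_id": points["device_id"].to_numpy(),
                       "value": points[value_col].to_numpy()})
    agg = df.groupby(["i", "j"]).agg(
        n_obs=("value", "size"),
        n_devices=("device_id", "nunique"),
        mean_increment=("value", "mean"),
    ).reset_index()
    agg["reported"] = (agg["n_obs"] >= min_obs) & (agg["n_devices"] >= min_devices)
    agg["quantile_class"] = pd.array([pd.NA] * len(agg), dtype="Int64")
    rep = agg["reported"]
    if rep.sum() >= 5:
        agg.loc[rep, "quantile_class"] = quantile_classes(
            agg.loc[rep, "mean_increment"].to_numpy())
    return agg


def quantile_classes(values: np.ndarray, k: int = 5) -> np.ndarray:
    """Classify values into k quantile classes (1..k), ~equal counts.

    Breaks are linear-interpolation quantiles at 1/k .. (k-1)/k; a value is
    assigned the lowest class whose interval contains it, so ties collapse
    downwards (all-identical input is entirely class 1).
    """
    v = np.asarray(values, dtype=float)
    if v.size < k:
        raise ValueError(f"need at least {k} values for {k} quantile classes")
    breaks = np.quantile(v, np.arange(1, k) / k, method="linear")
    return 1 + np.sum(v[:, None] > breaks[None, :], axis=1)


def coincidence_scatter(measurements: pd.DataFrame, grid: GridSpec | None = None,
                        cell_size: float = 50.0,
                        value_col: str = "pm25_cal") -> tuple[pd.DataFrame, dict]:
    """Between-device scatter where devices co-incide in a cell and hour.

    For every (cell, hour) crossed by >= 2 devices: the per-device mean
    concentration, their sample standard deviation, and the relative
    scatter (SD over the mean of the device means).  Returns the per-cell
    table and a summary dict with the campaign-mean relative scatter.
    """
    if grid is None:
        grid = GridSpec(cell_size=cell_size)
    i, j = project_point(measurements["lat"].to_numpy(),
                         measurements["lon"].to_numpy(), grid)
    df = pd.DataFrame({
        "i": i, "j": j,
        "hour": measurements["time"].dt.floor("h").to_numpy(),
        "device_id": measurements["device_id"].to_numpy(),
        "value": measurements[value_col].to_numpy(),
    })
    dev_means = (df.groupby(["i", "j", "hour", "device_id"])["value"]
                 .mean().reset_index())
    cells = dev_means.groupby(["i", "j", "hour"]).agg(
        n_devices=("device_id", "nunique"),
        mean_of_means=("value", "mean"),
        sd_across_devices=("value", lambda s: s.std(ddof=1)),
    ).reset_index()
    cells = cells.loc[cells["n_devices"] >= 2].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        cells["relative_scatter"] = np.where(
            cells["mean_of_means"] != 0,
            cells["sd_across_devices"] / cells["mean_of_means"], np.nan)
    summary = {
        "n_cells": int(len(cells)),
        "mean_relative_scatter": float(cells["relative_scatter"].mean())
        if len(cells) else np.nan,
    }
    return cells, summary


def cells_to_geojson(cells: pd.DataFrame, grid: GridSpec,
                     path: str | Path | None = None) -> dict:
    """Reported cells as a WGS84 GeoJSON FeatureCollection of polygons."""
    feats = []
    s = grid.cell_size
    ox, oy = grid.origin
    for _, row in cells.loc[cells["reported"]].iterrows():
        x0 = ox + row["i"] * s
        y0 = oy + row["j"] * s
        xs = np.array([x0, x0 + s, x0 + s, x0, x0])
        ys = np.array([y0, y0, y0 + s, y0 + s, y0])
        lat, lon = rd_to_wgs84(xs, ys)
        ring = [[round(float(lo), 7), round(float(la), 7)]
                for la, lo in zip(lat, lon)]
        qc = row["quantile_class"]
        feats.append({
            "type": "Feature",
            "properties": {
                "n_obs": int(row["n_obs"]),
                "n_devices": int(row["n_devices"]),
                "mean_increment": round(float(row["mean_increment"]), 4),
                "quantile_class": int(qc) if pd.notna(qc) else None,
            },
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    fc = {"type": "FeatureCollection", "features": feats}
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc
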