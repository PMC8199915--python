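"""Published benchmark values for the Utrecht 2020 mobile-sensor campaign.

The four-station Leave-Station-Out validation of that campaign is the
reference point for this package's report conventions: per-station means,
MAE, RMSE and Pearson correlation for raw and LSO-calibrated sensor data,
summarised by an unweighted column mean across stations.  The table below
holds the published per-station values; :func:`summarize_station_metrics`
applies the same column-mean convention used by
:func:`cyclepm.calibration.lso_validate`, so the summary row of any
validation report is directly comparable.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["utrecht2020_station_metrics", "summarize_station_metrics"]


def utrecht2020_station_metrics() -> pd.DataFrame:
    """Per-station validation metrics of the 2020 Utrecht campaign.

    Concentrations in ug/m3; one row per reference station.
    """
    rows = [
        # station, official, raw, lso, pearson_raw, pearson_lso,
        # mae_raw, mae_lso, rmse_raw, rmse_lso
        ("Kardinaal de Jong", 10.3, 8.0, 8.9, 0.86, 0.82, 3.8, 3.4, 4.3, 4.5),
        ("Griftpark",          9.3, 8.3, 9.1, 0.84, 0.81, 3.5, 3.2, 4.7, 4.6),
        ("Breukelen",          9.0, 7.9, 9.1, 0.82, 0.83, 3.6, 2.9, 4.9, 4.2),
        ("Cabauw",             8.8, 8.4, 10.0, 0.73, 0.75, 4.1, 3.6, 6.0, 5.4),
    ]
    cols = ["station_id", "mean_official", "mean_raw", "mean_lso",
            "pearson_raw", "pearson_lso", "mae_raw", "mae_lso",
            "rmse_raw", "rmse_lso"]
    return pd.DataFrame(rows, columns=cols).set_index("station_id")


def summarize_station_metrics(report: pd.DataFrame) -> pd.Series:
    """Unweighted column means across stations (the report 'average' row)."""
    df = report.drop(index="average", errors="ignore")
    return df.mean(numeric_only=True)
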