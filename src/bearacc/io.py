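"""Readers and writers for the pipeline's delimited-text formats.

All tables are plain CSV with ISO-8601 timestamps:

* accelerometry: ``timestamp, acc_x, acc_y, acc_z`` (g, 8 Hz collar export);
* annotation events: ``behavior, start, end`` (video-annotation export);
* GPS tracks: ``timestamp, x_m, y_m`` (planar metres) or
  ``timestamp, lat, lon`` (degrees);
* bear metadata: ``bear_id, year, demographic_group`` (plus free columns).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

ACCEL_COLUMNS = ["timestamp", "acc_x", "acc_y", "acc_z"]
EVENT_COLUMNS = ["behavior", "start", "end"]


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns {missing}")


def read_accel(path: str | Path) -> pd.DataFrame:
    """Read an accelerometry CSV; timestamps parsed, sorted by time."""
    df = pd.read_csv(path)
    _require(df, ACCEL_COLUMNS, "accelerometry")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def write_accel(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    out.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an annotation event CSV (behavior, start, end)."""
    df = pd.read_csv(path)
    _require(df, EVENT_COLUMNS, "annotation")
    for c in ("start", "end"):
        df[c] = pd.to_datetime(df[c])
    return df


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for c in ("start", "end"):
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    out.to_csv(path, index=False)


def read_gps(path: str | Path) -> pd.DataFrame:
    """Read a GPS track CSV (timestamp + x_m/y_m or lat/lon)."""
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise ValueError("GPS table is missing column ['timestamp']")
    if not ({"x_m", "y_m"} <= set(df.columns) or {"lat", "lon"} <= set(df.columns)):
        raise ValueError("GPS table needs x_m/y_m (planar metres) or lat/lon columns")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def write_gps(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the bear-metadata table (bear_id, year, demographic_group, ...)."""
    df = pd.read_csv(path)
    _require(df, ["bear_id", "demographic_group"], "bear metadata")
    return df
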