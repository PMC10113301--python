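"""CSV dialects used between pipeline stages.

Matrices are labeled CSVs with an optional leading metadata block of
``# key: value`` comment lines (bin edges, window, matrix id).  Visit-event
tables use the camera CSV layout (camera_id, date, time, pollinator, plant,
legitimate); nectar tables use one row per extraction.
"""

from __future__ import annotations

import json

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_visits",
    "write_visits",
    "read_nectar",
    "read_abundance",
    "read_traits",
]


def write_matrix(matrix: pd.DataFrame, path, metadata: dict | None = None) -> None:
    meta = dict(matrix.attrs)
    meta.update(metadata or {})
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {json.dumps(value)}\n")
        matrix.to_csv(fh)


def read_matrix(path) -> pd.DataFrame:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = json.loads(value.strip())
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), index_col=0)
    try:
        df.columns = [int(c) for c in df.columns]
    except (TypeError, ValueError):
        pass
    df.attrs.update(meta)
    return df


def write_visits(events: pd.DataFrame, path) -> None:
    out = events.copy()
    ts = pd.to_datetime(out.pop("timestamp"))
    out.insert(1, "date", ts.dt.strftime("%Y-%m-%d"))
    out.insert(2, "time", ts.dt.strftime("%H:%M:%S"))
    out.to_csv(path, index=False)


def read_visits(path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype={"camera_id": str})
    ts = pd.to_datetime(raw["date"] + " " + raw["time"])
    out = raw.drop(columns=["date", "time"])
    out.insert(1, "timestamp", ts)
    out["legitimate"] = out["legitimate"].astype(bool)
    return out


def read_nectar(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"plant", "individual", "flower", "slot", "volume_ul", "brix_pct", "temperature_c", "protocol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"nectar table missing columns: {sorted(missing)}")
    return df


def read_abundance(path) -> pd.DataFrame:
    """Monthly flower censuses: columns plant, month, flowers."""
    df = pd.read_csv(path, dtype={"month": str})
    missing = {"plant", "month", "flowers"} - set(df.columns)
    if missing:
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    return df


def read_traits(path) -> pd.Series:
    """Per-plant anther heights: columns plant, anther_height_cm."""
    df = pd.read_csv(path)
    missing = {"plant", "anther_height_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    return df.set_index("plant")["anther_height_cm"]
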