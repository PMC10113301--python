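"""From raw visit events to analysis matrices.

Camera streams yield one row per detected floral visit.  Three steps turn them
into the matrices the niche analysis consumes:

1. ``deduplicate_visits`` — drop non-legitimate visits and collapse detections
   less than 20 s apart (per camera, hummingbird and plant) into single
   independent visits.
2. ``build_trophic_matrix`` — hummingbird x plant counts of independent visits
   (matrix M1).
3. ``build_diel_matrix`` — hummingbird x hour-of-day bins (matrix M2), either
   the full observation day (06:00-18:00, 12 one-hour bins) or the morning
   only (06:00-12:00, 6 bins).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["deduplicate_visits", "build_trophic_matrix", "build_diel_matrix", "hour_of_day"]

#: grouping that defines visit independence; camera included because the 20-s
#: rule applies per focal flower/camera (exposed so the chaining behaviour can
#: be changed in config if desired)
DEDUP_GROUP = ["camera_id", "pollinator", "plant"]


def hour_of_day(ts: pd.Series) -> pd.Series:
    """Clock time as fractional hours (e.g. 06:30 -> 6.5)."""
    ts = pd.to_datetime(ts)
    return ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0


def deduplicate_visits(
    events: pd.DataFrame,
    min_gap_s: float = 20.0,
    group_cols: list[str] = DEDUP_GROUP,
) -> pd.DataFrame:
    """Keep independent legitimate visits only.

    Within each group an event is retained iff at least ``min_gap_s`` seconds
    elapsed since the previously *retained* event of that group (the gap is
    measured to the retained anchor, not the previous raw event, and the
    boundary is inclusive: a gap of exactly 20 s counts as independent).
    Non-legitimate events are dropped first.  The result is sorted by time.
    """
    if min_gap_s <= 0:
        raise ValueError("min_gap_s must be > 0")
    if events.empty:
        return events.copy()
    missing = events["timestamp"].isna()
    if missing.any():
        raise ValueError(f"events with missing timestamp at index {list(events.index[missing])}")
    ev = events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    if "legitimate" in ev.columns:
        ev = ev[ev["legitimate"].astype(bool)]
    ev = ev.sort_values(["timestamp", *group_cols], kind="mergesort")

    keep_idx: list = []
    for _, grp in ev.groupby(group_cols, sort=False):
        anchor = None
        for idx, ts in zip(grp.index, grp["timestamp"]):
            if anchor is None or (ts - anchor).total_seconds() >= min_gap_s:
                keep_idx.append(idx)
                anchor = ts
    out = ev.loc[keep_idx].sort_values(["timestamp", *group_cols], kind="mergesort")
    logger.info("deduplication: %d raw -> %d independent visits", len(events), len(out))
    return out.reset_index(drop=True)


def build_trophic_matrix(events: pd.DataFrame) -> pd.DataFrame:
    """Hummingbird x plant counts of independent visits (matrix M1)."""
    if events.empty:
        logger.warning("no events: returning empty interaction matrix")
        return pd.DataFrame(dtype=int).rename_axis(index="pollinator", columns="plant")
    m1 = pd.crosstab(events["pollinator"], events["plant"])
    return m1.rename_axis(index="pollinator", columns="plant")


def _bin_edges(window: str) -> np.ndarray:
    if window == "full_day":
        return np.arange(6, 19, dtype=float)  # 12 bins, 06..18
    if window == "morning":
        return np.arange(6, 13, dtype=float)  # 6 bins, 06..12
    raise ValueError(f"unknown window {window!r} (expected 'full_day' or 'morning')")


def build_diel_matrix(events: pd.DataFrame, window: str = "full_day") -> pd.DataFrame:
    """Hummingbird x hour-bin counts of independent visits (matrix M2).

    Full day: 12 one-hour bins [06,07), ..., [17,18]; the last bin is closed
    so an 18:00:00 event (dusk) is still counted.  Morning: 6 bins [06,07),
    ..., [11,12).  Events outside the window are excluded with a logged count.
    The matrix carries the bin left edges as integer columns and the full edge
    vector in ``attrs['bin_edges']``.
    """
    edges = _bin_edges(window)
    if events.empty:
        out = pd.DataFrame(columns=edges[:-1].astype(int), dtype=int)
        out.attrs["bin_edges"] = edges.tolist()
        out.attrs["window"] = window
        return out.rename_axis(index="pollinator", columns="hour")
    hours = hour_of_day(events["timestamp"]).to_numpy()
    idx = np.digitize(hours, edges) - 1
    if window == "full_day":
        idx[np.isclose(hours, edges[-1])] = len(edges) - 2  # 18:00:00 exactly
    inside = (idx >= 0) & (idx <= len(edges) - 2)
    n_out = int((~inside).sum())
    if n_out:
        logger.info("%d events outside the %s window excluded", n_out, window)
    sub = events.loc[inside]
    out = pd.crosstab(sub["pollinator"], pd.Series(edges[idx[inside]].astype(int), index=sub.index))
    out = out.reindex(columns=edges[:-1].astype(int), fill_value=0)
    out.attrs["bin_edges"] = edges.tolist()
    out.attrs["window"] = window
    return out.rename_axis(index="pollinator", columns="hour")
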