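"""Telemetry track quality control.

Raw Argos fixes are sorted per tag, screened with an iterative
forward/backward averaging speed filter, and reduced to one best position per
UTC day (location class 3 > 2 > 1 > 0 > A > B, then proximity to midday).

The speed filter computes, for every retained fix, the root-mean-square of
travel speeds to up to ``window`` retained neighbours on each side; the fix
with the worst RMS exceeding ``vmax`` is removed and the speeds recomputed,
until no fix exceeds the limit.  Track endpoints, which only have one-sided
speeds, are removed only when every available one-sided speed exceeds the
limit.  Removal order is deterministic: worst RMS first, ties broken by
earlier timestamp.
"""

from __future__ import annotations

import logging
from datetime import timezone

import numpy as np
import pandas as pd

from .config import ARGOS_CLASSES
from .geodesy import geodesic_distance, vincenty_distance

log = logging.getLogger(__name__)

DEFAULT_VMAX_MS = 5.0
DEFAULT_WINDOW = 2

_QUALITY_RANK = {c: i for i, c in enumerate(ARGOS_CLASSES)}  # 3 best ... B worst


def read_fixes(path_or_df) -> pd.DataFrame:
    """Read and validate a raw fix table (tag_id, timestamp, lat, lon, quality).

    Timestamps are parsed as UTC; rows are sorted by (tag, time).  Duplicate
    timestamps within a tag are dropped (first kept, logged).
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, dtype={"tag_id": str, "quality": str})
    required = ["tag_id", "timestamp", "lat", "lon", "quality"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"fix table missing columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df["quality"] = df["quality"].astype(str)
    bad_q = set(df["quality"]) - set(ARGOS_CLASSES)
    if bad_q:
        raise ValueError(f"unknown Argos quality classes: {sorted(bad_q)}")
    if (df["lat"].abs() > 90).any():
        raise ValueError("latitudes outside [-90, 90]")
    if ((df["lon"] < -180) | (df["lon"] >= 360)).any():
        raise ValueError("longitudes outside [-180, 360)")
    df.loc[df["lon"] >= 180, "lon"] -= 360.0
    df = df.sort_values(["tag_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(["tag_id", "timestamp"])
    if dup.any():
        log.warning("dropping %d duplicate-timestamp fixes", int(dup.sum()))
        df = df[~dup].reset_index(drop=True)
    return df


def _speed_table(ts: np.ndarray, lat: np.ndarray, lon: np.ndarray, window: int) -> np.ndarray:
    """Speeds (m/s) from each fix to up to ``window`` neighbours per side.

    Returns an (n, 2*window) array, columns = [back_w..back_1, fwd_1..fwd_w],
    NaN where the neighbour does not exist.  Vectorized over the track.
    """
    n = len(ts)
    table = np.full((n, 2 * window), np.nan)
    for k in range(1, window + 1):
        if n <= k:
            continue
        d = np.atleast_1d(vincenty_distance(lat[:-k], lon[:-k], lat[k:], lon[k:]))
        dt = ts[k:] - ts[:-k]
        s = np.where(dt > 0, d / np.where(dt > 0, dt, 1.0), np.nan)
        table[k:, window - k] = s       # backward speed of fix i to i-k
        table[:-k, window + k - 1] = s  # forward speed of fix i to i+k
    return table


def speed_filter(
    fixes: pd.DataFrame,
    vmax: float = DEFAULT_VMAX_MS,
    window: int = DEFAULT_WINDOW,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iteratively remove fixes implying unrealistic travel speeds.

    Operates per tag; returns ``(kept, removed)`` partitions of the input
    rows (coordinates untouched, order preserved).  Raises if the filter
    degenerates (all interior fixes of a tag removed).
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    df = read_fixes(fixes)
    kept_parts, removed_parts = [], []
    for tag, grp in df.groupby("tag_id", sort=True):
        grp = grp.reset_index(drop=True)
        if len(grp) < 3:
            kept_parts.append(grp)
            continue
        ts = grp["timestamp"].astype("int64").to_numpy() / 1e9
        lat = grp["lat"].to_numpy()
        lon = grp["lon"].to_numpy()
        active = list(range(len(grp)))
        removed_idx = []
        while True:
            if len(active) < 3:
                raise ValueError(f"filter degenerate for tag {tag}; vmax too low")
            idx = np.array(active)
            table = _speed_table(ts[idx], lat[idx], lon[idx], window)
            has_back = ~np.all(np.isnan(table[:, :window]), axis=1)
            has_fwd = ~np.all(np.isnan(table[:, window:]), axis=1)
            with np.errstate(invalid="ignore"):
                rms = np.sqrt(np.nanmean(np.square(table), axis=1))
                all_exceed = np.nanmin(table, axis=1) > vmax
            candidate = rms > vmax
            # one-sided (endpoint) fixes: every available speed must exceed
            one_sided = ~(has_back & has_fwd)
            candidate &= ~one_sided | all_exceed
            candidate &= has_back | has_fwd
            if not candidate.any():
                break
            # worst RMS first; argmax returns the earliest index on ties
            worst_pos = int(np.argmax(np.where(candidate, rms, -np.inf)))
            removed_idx.append(active.pop(worst_pos))
        kept_parts.append(grp.iloc[sorted(active)])
        if removed_idx:
            removed_parts.append(grp.iloc[sorted(removed_idx)])
        log.info("tag %s: kept %d, removed %d fixes", tag, len(active), len(removed_idx))
    kept = pd.concat(kept_parts, ignore_index=True) if kept_parts else df.iloc[0:0]
    removed = (
        pd.concat(removed_parts, ignore_index=True)
        if removed_parts
        else df.iloc[0:0]
    )
    return kept, removed


def select_daily(fixes: pd.DataFrame) -> pd.DataFrame:
    """One best position per tag per UTC day.

    Within a day, restrict to the best available Argos class
    (3 > 2 > 1 > 0 > A > B), then pick the fix closest to 12:00 UTC; ties go
    to the earlier timestamp.
    """
    df = read_fixes(fixes)
    if len(df) == 0:
        return pd.DataFrame(
            columns=["tag_id", "date", "lat", "lon", "source_quality", "source_timestamp"]
        )
    df["date"] = df["timestamp"].dt.date
    df["_rank"] = df["quality"].map(_QUALITY_RANK)
    noon = df["timestamp"].dt.normalize() + pd.Timedelta(hours=12)
    df["_off"] = (df["timestamp"] - noon).abs()
    # stable sort: best quality tier first, then midday proximity, then time
    df = df.sort_values(
        ["tag_id", "date", "_rank", "_off", "timestamp"], kind="mergesort"
    )
    picks = df.groupby(["tag_id", "date"], sort=True).head(1)
    out = pd.DataFrame(
        {
            "tag_id": picks["tag_id"].to_numpy(),
            "date": picks["date"].astype(str).to_numpy(),
            "lat": picks["lat"].to_numpy(),
            "lon": picks["lon"].to_numpy(),
            "source_quality": picks["quality"].to_numpy(),
            "source_timestamp": [
                t.tz_convert(timezone.utc).isoformat() for t in picks["timestamp"]
            ],
        }
    )
    return out.sort_values(["tag_id", "date"], kind="mergesort").reset_index(drop=True)


def track_distances_m(daily: pd.DataFrame) -> pd.DataFrame:
    """Vincenty distance (m) between successive daily positions per tag."""
    out = []
    for tag, grp in daily.groupby("tag_id", sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        if len(grp) < 2:
            continue
        d = vincenty_distance(
            grp["lat"].to_numpy()[:-1],
            grp["lon"].to_numpy()[:-1],
            grp["lat"].to_numpy()[1:],
            grp["lon"].to_numpy()[1:],
        )
        for i in range(len(grp) - 1):
            out.append(
                {
                    "tag_id": tag,
                    "date_from": grp["date"].iloc[i],
                    "date_to": grp["date"].iloc[i + 1],
                    "distance_m": float(np.atleast_1d(d)[i]),
                }
            )
    return pd.DataFrame(out, columns=["tag_id", "date_from", "date_to", "distance_m"])


def apply_end_dates(daily: pd.DataFrame, end_dates: dict[str, str] | None) -> pd.DataFrame:
    """Trim each tag's daily positions at a config-supplied detachment date."""
    if not end_dates:
        return daily
    keep = pd.Series(True, index=daily.index)
    for tag, end in end_dates.items():
        keep &= ~((daily["tag_id"] == tag) & (daily["date"] > str(end)))
    return daily[keep].reset_index(drop=True)
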