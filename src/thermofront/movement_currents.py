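"""Zonal movement speeds versus gridded surface currents.

Daily-position pairs separated by at most 3 days yield a zonal movement
speed (signed east-west geodesic distance at the pair's mean latitude over
the elapsed time).  Each pair is matched with the zonal surface current at
the single grid node — in space and time — nearest the pair midpoint, and
agreement is summarised by paired speed histograms and the coefficient of
determination r^2 (squared Pearson correlation: the fraction of variance in
animal speeds explained by the currents).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .geodesy import zonal_distance_km

log = logging.getLogger(__name__)

MAX_PAIR_GAP_DAYS = 3.0
DEFAULT_SPEED_BIN_MS = 0.2


@dataclass
class MatchupRecord:
    tag_id: str
    date_from: str
    date_to: str
    dt_s: float
    mean_lat: float
    mid_lon: float
    zonal_shark_speed: float    # m/s, positive east
    zonal_current_speed: float  # m/s, positive east


def zonal_speed(
    lat1: float, lon1: float, t1, lat2: float, lon2: float, t2
) -> float:
    """Zonal movement speed (m/s, positive east) between two positions.

    The east-west distance is measured along the parallel at the pair's mean
    latitude (geodesic, wrap-safe across the antimeridian) and divided by
    the elapsed time.  Raises on zero elapsed time.
    """
    dt = (pd.Timestamp(t2) - pd.Timestamp(t1)).total_seconds()
    if dt == 0:
        raise ValueError("zero time separation between positions")
    mean_lat = 0.5 * (lat1 + lat2)
    dist_km = float(zonal_distance_km(mean_lat, lon1, lon2))
    # |dt|: a pair presented in reverse order yields the negated speed
    return dist_km * 1000.0 / abs(dt)


def build_pairs(daily: pd.DataFrame, max_gap_days: float = MAX_PAIR_GAP_DAYS) -> tuple[pd.DataFrame, int]:
    """Consecutive daily-position pairs per tag with gap <= ``max_gap_days``.

    Returns the eligible pairs and the count of skipped (too-wide) pairs, so
    eligible + skipped = total consecutive pairs.
    """
    has_ts = "source_timestamp" in daily.columns
    rows = []
    n_skipped = 0
    for tag, grp in daily.groupby("tag_id", sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        for i in range(len(grp) - 1):
            a, b = grp.iloc[i], grp.iloc[i + 1]
            if b["date"] <= a["date"]:
                raise ValueError(f"non-increasing dates for tag {tag}")
            if has_ts:
                # elapsed time between the actual selected fixes
                t1 = pd.Timestamp(a["source_timestamp"])
                t2 = pd.Timestamp(b["source_timestamp"])
            else:
                t1 = pd.Timestamp(a["date"]) + pd.Timedelta(hours=12)
                t2 = pd.Timestamp(b["date"]) + pd.Timedelta(hours=12)
            dt_s = (t2 - t1).total_seconds()
            if dt_s <= 0 or dt_s > max_gap_days * 86400.0:
                n_skipped += 1
                continue
            rows.append(
                {
                    "tag_id": tag,
                    "date_from": a["date"],
                    "date_to": b["date"],
                    "t_from": t1.isoformat(),
                    "t_to": t2.isoformat(),
                    "lat1": a["lat"],
                    "lon1": a["lon"],
                    "lat2": b["lat"],
                    "lon2": b["lon"],
                    "dt_s": dt_s,
                }
            )
    return pd.DataFrame(rows), n_skipped


def matchup(pairs: pd.DataFrame, u: xr.DataArray) -> tuple[list[MatchupRecord], int]:
    """Match each eligible pair with the nearest-node zonal current.

    The current is taken at the grid node nearest the pair midpoint in
    space, from the time slice nearest the pair's mid-date; exact ties go to
    the lower index.  Pairs landing on masked nodes are dropped and counted.
    Returns (records, n_masked).
    """
    records: list[MatchupRecord] = []
    n_masked = 0
    lat_c = u.lat.values
    lon_c = u.lon.values
    times = u.time.values
    for _, p in pairs.iterrows():
        mean_lat = 0.5 * (p["lat1"] + p["lat2"])
        dlon = (p["lon2"] - p["lon1"] + 180.0) % 360.0 - 180.0
        mid_lon = ((p["lon1"] + dlon / 2.0 + 180.0) % 360.0) - 180.0
        t_from = p["t_from"] if "t_from" in p else p["date_from"]
        t_to = p["t_to"] if "t_to" in p else p["date_to"]
        mid_time = pd.Timestamp(t_from) + pd.Timedelta(seconds=p["dt_s"] / 2.0)
        if mid_time.tzinfo is not None:
            mid_time = mid_time.tz_convert(None)
        it = int(np.argmin(np.abs(times - np.datetime64(mid_time))))
        iy = int(np.argmin(np.abs(lat_c - mean_lat)))
        ix = int(np.argmin(np.abs(lon_c - mid_lon)))
        u_val = float(u.values[it, iy, ix])
        if np.isnan(u_val):
            n_masked += 1
            continue
        speed = zonal_speed(p["lat1"], p["lon1"], t_from, p["lat2"], p["lon2"], t_to)
        records.append(
            MatchupRecord(
                tag_id=p["tag_id"],
                date_from=p["date_from"],
                date_to=p["date_to"],
                dt_s=float(p["dt_s"]),
                mean_lat=float(mean_lat),
                mid_lon=float(mid_lon),
                zonal_shark_speed=speed,
                zonal_current_speed=u_val,
            )
        )
    if n_masked:
        log.info("dropped %d pairs on masked current nodes", n_masked)
    return records, n_masked


def agreement(records: list[MatchupRecord], bin_ms: float = DEFAULT_SPEED_BIN_MS) -> dict:
    """Paired speed histograms and r^2 between animal and current speeds."""
    if len(records) < 3:
        raise ValueError("need at least 3 matchup records")
    shark = np.array([r.zonal_shark_speed for r in records])
    curr = np.array([r.zonal_current_speed for r in records])
    lo = np.floor(min(shark.min(), curr.min()) / bin_ms) * bin_ms
    hi = np.ceil(max(shark.max(), curr.max()) / bin_ms) * bin_ms + bin_ms
    edges = np.arange(lo, hi + bin_ms / 2, bin_ms)
    shark_hist, _ = np.histogram(shark, bins=edges)
    curr_hist, _ = np.histogram(curr, bins=edges)
    if shark.std() == 0 or curr.std() == 0:
        r2 = None
        reason = "zero variance in speed series"
    else:
        r, _ = stats.pearsonr(shark, curr)
        r2 = float(r**2)
        reason = None
    out = {
        "n": int(len(records)),
        "r2": r2,
        "bin_edges": edges,
        "shark_hist": shark_hist,
        "current_hist": curr_hist,
        "r2_definition": "squared Pearson correlation",
    }
    if reason:
        out["r2_reason"] = reason
    return out


def records_to_frame(records: list[MatchupRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tag_id": r.tag_id,
                "date_from": r.date_from,
                "date_to": r.date_to,
                "dt_s": r.dt_s,
                "mean_lat": round(r.mean_lat, 6),
                "mid_lon": round(r.mid_lon, 6),
                "zonal_shark_speed_ms": round(r.zonal_shark_speed, 6),
                "zonal_current_speed_ms": round(r.zonal_current_speed, 6),
            }
            for r in records
        ],
        columns=[
            "tag_id", "date_from", "date_to", "dt_s", "mean_lat", "mid_lon",
            "zonal_shark_speed_ms", "zonal_current_speed_ms",
        ],
    )
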