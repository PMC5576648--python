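"""Gridded SST handling: 3-day composites, long-term means, and
animal-centric section extraction.

Fields are regular lat/lon/time grids held as :class:`xarray.DataArray`
(dims ``time, lat, lon``, cell-centre registration, NaN as the missing-value
mask).  Sections are 1-D SST profiles along a grid column (meridional) or
row (zonal) through an animal position, re-referenced to geodesic distance
from the animal: 0 at the animal, positive north (meridional) or east
(zonal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .geodesy import meridional_distance_km, zonal_distance_km

log = logging.getLogger(__name__)

DEFAULT_HALF_LENGTH_KM = 800.0
DEFAULT_MIN_SPAN_KM = 300.0


@dataclass
class FrontSection:
    """SST along one grid line through an animal position.

    ``distance_km`` is strictly increasing, 0 at the animal (value bilinearly
    interpolated there); positive north for meridional sections, positive
    east for zonal ones.
    """

    tag_id: str
    date: str
    anchor_lat: float
    anchor_lon: float
    orientation: str  # "meridional" | "zonal"
    coords: np.ndarray  # sample lat (meridional) or lon (zonal), degrees
    distance_km: np.ndarray
    sst_c: np.ndarray
    flags: list[str] = field(default_factory=list)

    def value_at(self, distance_km: float) -> float:
        return float(np.interp(distance_km, self.distance_km, self.sst_c))


def composite_3day(daily: xr.DataArray, center_date) -> xr.DataArray:
    """Per-cell mean of the three daily slices centred on ``center_date``.

    Cells are averaged over the available, unmasked slices; a cell is masked
    only if masked in every slice of the window.  At the edges of the record
    the available subset (>= 1 slice) is used.
    """
    center = pd.Timestamp(center_date)
    times = pd.to_datetime(daily.time.values)
    sel = np.abs((times - center) / pd.Timedelta(days=1)) <= 1.0
    if not sel.any():
        raise ValueError(f"no daily slices within 1 day of {center.date()}")
    window = daily.isel(time=np.nonzero(sel)[0])
    out = window.mean("time", skipna=True)
    out = out.assign_coords(time=center)
    out.attrs.update(daily.attrs)
    return out


def composite_series(daily: xr.DataArray) -> xr.DataArray:
    """Rolling 3-day composites centred on every day of the record."""
    out = daily.rolling(time=3, center=True, min_periods=1).mean()
    out.attrs.update(daily.attrs)
    return out


def nearest_time_index(field: xr.DataArray, date) -> int:
    """Index of the field time nearest ``date``; ties go to the earlier slice."""
    target = pd.Timestamp(date)
    times = pd.to_datetime(field.time.values)
    off = np.abs((times - target).values)
    return int(np.argmin(off))  # argmin takes the first (earlier) on ties


def long_term_mean(daily: xr.DataArray, period: slice | None = None) -> xr.DataArray:
    """Per-cell mean over unmasked slices in ``period`` (a time slice)."""
    sub = daily.sel(time=period) if period is not None else daily
    if sub.sizes.get("time", 0) == 0:
        raise ValueError("empty period for long-term mean")
    out = sub.mean("time", skipna=True)
    out.attrs.update(daily.attrs)
    return out


def extract_section(
    field: xr.DataArray,
    lat: float,
    lon: float,
    orientation: str = "meridional",
    half_length_km: float = DEFAULT_HALF_LENGTH_KM,
    tag_id: str = "",
    date: str = "",
    min_span_km: float = DEFAULT_MIN_SPAN_KM,
) -> FrontSection:
    """Extract an animal-centric SST section from a (lat, lon) field.

    The section follows the grid column (meridional) or row (zonal) through
    the animal position: grid-spacing samples interpolated linearly to the
    animal's exact off-grid longitude (resp. latitude), plus one sample
    bilinearly interpolated at the animal itself, at distance 0.  Coordinate
    offsets become km via WGS-84 geodesic distance from the anchor, and the
    section is clipped at ``half_length_km`` and at domain/mask edges.
    """
    if orientation not in ("meridional", "zonal"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if "time" in field.dims:
        raise ValueError("pass a single time slice (e.g. a 3-day composite)")
    lats = field.lat.values
    lons = field.lon.values
    if not (lats.min() <= lat <= lats.max() and lons.min() <= lon <= lons.max()):
        raise ValueError(f"position ({lat}, {lon}) outside the field domain")

    anchor_val = float(field.interp(lat=lat, lon=lon).values)
    if np.isnan(anchor_val):
        raise ValueError("anchor invalid: animal position is masked (land?)")

    if orientation == "meridional":
        line = field.interp(lon=lon).values  # (nlat,)
        coords = lats
        dist = meridional_distance_km(lat, lats)
    else:
        line = field.interp(lat=lat).values  # (nlon,)
        coords = lons
        dist = zonal_distance_km(lat, lon, lons)

    keep = np.abs(dist) <= half_length_km
    coords, dist, line = coords[keep], np.asarray(dist)[keep], line[keep]
    # insert the exact-anchor sample at distance 0
    ins = int(np.searchsorted(dist, 0.0))
    at_node = ins < len(dist) and np.isclose(dist[ins], 0.0, atol=1e-9)
    if at_node:
        line = line.copy()
        line[ins] = anchor_val
    else:
        dist = np.insert(dist, ins, 0.0)
        coords = np.insert(coords, ins, lat if orientation == "meridional" else lon)
        line = np.insert(line, ins, anchor_val)

    valid = ~np.isnan(line)
    flags: list[str] = []
    if not valid.all():
        # clip at the nearest masked cell on each side of the animal
        i0 = int(np.searchsorted(dist, 0.0))
        lo, hi = 0, len(line)
        bad = np.nonzero(~valid)[0]
        for b in bad:
            if b < i0:
                lo = max(lo, b + 1)
            elif b > i0:
                hi = min(hi, b)
        coords, dist, line = coords[lo:hi], dist[lo:hi], line[lo:hi]
        flags.append("clipped_at_mask")
    if dist.max() - dist.min() < 2 * min_span_km or -dist.min() < min_span_km or dist.max() < min_span_km:
        flags.append("short_section")
        log.warning(
            "section for %s %s spans [%.0f, %.0f] km (< %.0f km per side)",
            tag_id, date, dist.min(), dist.max(), min_span_km,
        )
    return FrontSection(
        tag_id=tag_id,
        date=str(date),
        anchor_lat=float(lat),
        anchor_lon=float(lon),
        orientation=orientation,
        coords=coords,
        distance_km=dist,
        sst_c=line,
        flags=flags,
    )


def sections_to_frame(sections: list[FrontSection]) -> pd.DataFrame:
    """Tidy long-format table (tag_id, date, distance_km, sst_c) of sections."""
    rows = []
    for s in sections:
        for d, v in zip(s.distance_km, s.sst_c):
            rows.append(
                {
                    "tag_id": s.tag_id,
                    "date": s.date,
                    "orientation": s.orientation,
                    "distance_km": round(float(d), 4),
                    "sst_c": round(float(v), 5),
                }
            )
    return pd.DataFrame(rows, columns=["tag_id", "date", "orientation", "distance_km", "sst_c"])
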