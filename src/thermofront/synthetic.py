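"""Synthetic ocean fields, animal tracks, and tag records.

The generator emulates the data structure the analysis assumes: a meandering
equatorial (or coastal) upwelling front in daily gridded SST, a westward
surface jet on the front base at OSCAR-like resolution, Argos-like telemetry
fixes from animals moving through the fields, and 12-hour time-at-temperature
summaries.  Every quantity the analysis is supposed to recover (true
positions, true percent-distance along the front) is also emitted as a
ground-truth channel that only tests consume.

All randomness flows from ``ScenarioConfig.seed``; identical config and seed
give bit-identical outputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from .config import ARGOS_CLASSES, ScenarioConfig
from .geodesy import (
    latitude_at_meridional_offset,
    meridional_distance_km,
)
from .tat_analysis import TAT_BIN_EDGES, tat_bin_columns

log = logging.getLogger(__name__)

KM_PER_DEG_LON_EQ = 111.32


def _km_per_deg_lon(lat) -> np.ndarray | float:
    return KM_PER_DEG_LON_EQ * np.cos(np.radians(lat))


# ---------------------------------------------------------------------------
# front geometry (analytic ground truth)
# ---------------------------------------------------------------------------

def front_base_lat(cfg: ScenarioConfig, lon, t_days):
    """Latitude of the temperature minimum at ``lon`` and time ``t_days``.

    The meander is ``A sin(2 pi x/lambda - 2 pi t/P)`` in km, with an optional
    second harmonic for vortex-like distortion, converted to degrees at the
    mean front latitude.
    """
    f = cfg.front
    x_km = (np.asarray(lon, dtype=float) - cfg.domain.lon_min) * _km_per_deg_lon(f.mean_lat)
    phase = 2.0 * np.pi * (x_km / f.meander_wavelength_km - np.asarray(t_days, dtype=float) / f.meander_period_days)
    disp_km = f.meander_amp_km * (np.sin(phase) + f.second_harmonic_frac * np.sin(2.0 * phase))
    return f.mean_lat + disp_km / 110.6


def front_base_lon(cfg: ScenarioConfig, lat, t_days):
    """Longitude of the coastal-upwelling temperature minimum (coastal mode)."""
    f, p = cfg.front, cfg.plume
    y_km = (np.asarray(lat, dtype=float) - p.axis_lat) * 110.6
    phase = 2.0 * np.pi * (y_km / f.meander_wavelength_km - np.asarray(t_days, dtype=float) / f.meander_period_days)
    disp_km = f.meander_amp_km * (np.sin(phase) + f.second_harmonic_frac * np.sin(2.0 * phase))
    return p.coast_lon - (disp_km + 0.5 * p.offshore_decay_km) / _km_per_deg_lon(lat)


def _profile(cfg: ScenarioConfig, d_km):
    """Piecewise-linear SST as a function of km poleward/offshore of the base."""
    f = cfg.front
    s_south = f.south_gradient_c_per_100km / 100.0
    s_back = f.background_gradient_c_per_1000km / 1000.0
    rise = (f.t_north - f.t_min) / f.width_km
    d = np.asarray(d_km, dtype=float)
    return np.where(
        d < 0,
        f.t_min + s_south * (-d),
        np.where(d <= f.width_km, f.t_min + rise * d, f.t_north + s_back * (d - f.width_km)),
    )


def true_percent_distance(cfg: ScenarioConfig, lat, lon, t_days):
    """Analytic percent distance of a position between the two front edges.

    0 at the temperature minimum, 100 at the poleward/offshore end of the
    linear frontal rise (the slope break); may fall outside [0, 100].
    """
    if cfg.orientation == "equatorial":
        base = front_base_lat(cfg, lon, t_days)
        d_km = meridional_distance_km(base, lat)
    else:
        base = front_base_lon(cfg, lat, t_days)
        d_km = (base - np.asarray(lon, dtype=float)) * _km_per_deg_lon(lat)  # positive west
    return 100.0 * d_km / cfg.front.width_km


# ---------------------------------------------------------------------------
# gridded fields
# ---------------------------------------------------------------------------

def _time_axis(cfg: ScenarioConfig, step_days: float, offset_days: float = 0.0):
    start = pd.Timestamp(cfg.domain.start_date, tz=None)
    t = np.arange(offset_days, cfg.domain.n_days, step_days, dtype=float)
    times = start + pd.to_timedelta(t, unit="D")
    return t, times


def generate_sst_field(cfg: ScenarioConfig) -> xr.DataArray:
    """Daily SST on the scenario grid with CF-style coordinates (degC)."""
    cfg.validate()
    dom = cfg.domain
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    lats = np.arange(dom.lat_min, dom.lat_max + dom.grid_deg / 2, dom.grid_deg)
    lons = np.arange(dom.lon_min, dom.lon_max + dom.grid_deg / 2, dom.grid_deg)
    t_days, times = _time_axis(cfg, 1.0)

    data = np.empty((len(t_days), len(lats), len(lons)))
    if cfg.orientation == "equatorial":
        for i, t in enumerate(t_days):
            base = front_base_lat(cfg, lons, t)  # (nlon,)
            d_km = meridional_distance_km(base[None, :], lats[:, None])
            data[i] = _profile(cfg, d_km)
    else:
        month_frac = t_days / 30.44
        for i, t in enumerate(t_days):
            base = front_base_lon(cfg, lats, t)  # (nlat,)
            d_km = (base[:, None] - lons[None, :]) * _km_per_deg_lon(lats)[:, None]
            data[i] = _profile(cfg, d_km) + cfg.plume.warming_c_per_month * month_frac[i]

    if cfg.front.noise_sd_c > 0:
        data += rng.normal(0.0, cfg.front.noise_sd_c, size=data.shape)

    da = xr.DataArray(
        data,
        dims=("time", "lat", "lon"),
        coords={"time": times, "lat": lats, "lon": lons},
        name="sst",
        attrs={"units": "degC", "long_name": "sea surface temperature"},
    )
    da.lat.attrs.update(units="degrees_north", standard_name="latitude")
    da.lon.attrs.update(units="degrees_east", standard_name="longitude")
    return da


def generate_current_field(cfg: ScenarioConfig) -> xr.DataArray:
    """Zonal surface current u (m s-1, positive east) on a 1/3-deg, 5-day grid.

    A westward jet centred on the front base latitude with Gaussian meridional
    decay, plus white noise.
    """
    cfg.validate()
    dom, cur = cfg.domain, cfg.current
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 12]))
    lats = np.arange(dom.lat_min, dom.lat_max + cur.grid_deg / 2, cur.grid_deg)
    lons = np.arange(dom.lon_min, dom.lon_max + cur.grid_deg / 2, cur.grid_deg)
    t_days, times = _time_axis(cfg, float(cur.time_step_days), offset_days=2.0)

    data = np.empty((len(t_days), len(lats), len(lons)))
    for i, t in enumerate(t_days):
        base = front_base_lat(cfg, lons, t)
        dy_km = meridional_distance_km(base[None, :], lats[:, None])
        data[i] = -cur.core_westward_ms * np.exp(-0.5 * (dy_km / cur.meridional_scale_km) ** 2)
    if cur.noise_sd_ms > 0:
        data += rng.normal(0.0, cur.noise_sd_ms, size=data.shape)

    da = xr.DataArray(
        data,
        dims=("time", "lat", "lon"),
        coords={"time": times, "lat": lats, "lon": lons},
        name="u",
        attrs={"units": "m s-1", "long_name": "zonal surface current", "positive": "eastward"},
    )
    da.lat.attrs.update(units="degrees_north", standard_name="latitude")
    da.lon.attrs.update(units="degrees_east", standard_name="longitude")
    return da


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def _nearest_index(coord: np.ndarray, value: float) -> int:
    return int(np.argmin(np.abs(coord - value)))


def _u_at(u: xr.DataArray, lat: float, lon: float, t_days: float, t_axis: np.ndarray) -> float:
    it = _nearest_index(t_axis, t_days)
    iy = _nearest_index(u.lat.values, lat)
    ix = _nearest_index(u.lon.values, lon)
    return float(u.values[it, iy, ix])


def generate_tracks(
    cfg: ScenarioConfig, sst: xr.DataArray, u: xr.DataArray
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate animal tracks and emit Argos-like fixes.

    Returns ``(fixes, truth_daily, truth_fixes)``:

    * ``fixes`` — tag_id, timestamp, lat, lon, quality (the analysis input);
    * ``truth_daily`` — per animal-day true midday position and true percent
      distance (ground truth, tests only);
    * ``truth_fixes`` — per emitted fix the true position and outlier flag.

    Movement modes: ``passive`` (zonal advection by u), ``front-biased``
    (zonal random walk + meridional relaxation toward the latitude whose
    percent distance equals a per-animal target), ``independent`` (unbiased
    random walk).  Animals leaving the domain have their tracks truncated
    with a logged warning.
    """
    cfg.validate()
    dom, trk = cfg.domain, cfg.track
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    start = pd.Timestamp(dom.start_date)
    u_t_axis = (u.time.values - np.datetime64(start)) / np.timedelta64(1, "D")
    classes = list(ARGOS_CLASSES)
    probs = np.array([trk.quality_probs.get(c, 0.0) for c in classes])
    probs = probs / probs.sum()

    lon_lo = dom.lon_min + 0.2 * (dom.lon_max - dom.lon_min)
    lon_hi = dom.lon_max - 0.2 * (dom.lon_max - dom.lon_min)

    fix_rows, daily_rows, truth_fix_rows = [], [], []
    for a in range(trk.n_animals):
        tag = f"SYN-{a+1:02d}"
        lon = float(rng.uniform(lon_lo, lon_hi))
        target_pct = float(rng.normal(trk.target_pct_mean, trk.target_pct_sd))
        if cfg.orientation == "equatorial":
            if trk.mode == "passive":
                span_deg = 2.0 * cfg.current.meridional_scale_km / 110.6
                lat = float(cfg.front.mean_lat + rng.uniform(-span_deg, span_deg))
            else:
                base0 = float(front_base_lat(cfg, lon, 0.0))
                lat = float(
                    latitude_at_meridional_offset(base0, target_pct / 100.0 * cfg.front.width_km)
                )
        else:
            lat = float(cfg.plume.axis_lat + rng.uniform(-1.0, 1.0))
            base0 = float(front_base_lon(cfg, lat, 0.0))
            lon = base0 - target_pct / 100.0 * cfg.front.width_km / _km_per_deg_lon(lat)

        # daily true positions at 12:00 UTC
        lats_true, lons_true = [], []
        truncated = False
        for d in range(trk.duration_days):
            t = d + 0.5
            lats_true.append(lat)
            lons_true.append(lon)
            if trk.mode == "passive":
                u_val = _u_at(u, lat, lon, t, u_t_axis)
                lon = lon + u_val * 86.4 / _km_per_deg_lon(lat)
            elif trk.mode == "independent":
                lon = lon + rng.normal(0.0, trk.zonal_step_sd_km) / _km_per_deg_lon(lat)
                lat = lat + rng.normal(0.0, trk.zonal_step_sd_km) / 110.6
            else:  # front-biased
                if cfg.orientation == "equatorial":
                    lon = lon + rng.normal(0.0, trk.zonal_step_sd_km) / _km_per_deg_lon(lat)
                    base = float(front_base_lat(cfg, lon, t + 1.0))
                    lat_target = float(
                        latitude_at_meridional_offset(base, target_pct / 100.0 * cfg.front.width_km)
                    )
                    lat = lat + trk.relax_rate * (lat_target - lat) + rng.normal(
                        0.0, trk.meridional_noise_km
                    ) / 110.6
                else:
                    lat = lat + rng.normal(0.0, trk.zonal_step_sd_km) / 110.6
                    base = float(front_base_lon(cfg, lat, t + 1.0))
                    lon_target = base - target_pct / 100.0 * cfg.front.width_km / _km_per_deg_lon(lat)
                    lon = lon + trk.relax_rate * (lon_target - lon) + rng.normal(
                        0.0, trk.meridional_noise_km
                    ) / _km_per_deg_lon(lat)
            if not (dom.lat_min <= lat <= dom.lat_max and dom.lon_min <= lon <= dom.lon_max):
                log.warning("animal %s left the domain on day %d; track truncated", tag, d + 1)
                truncated = True
                break
        n_days = len(lats_true)
        lats_true = np.array(lats_true)
        lons_true = np.array(lons_true)
        t_days_true = np.arange(n_days) + 0.5

        pct_true = true_percent_distance(cfg, lats_true, lons_true, t_days_true)
        for d in range(n_days):
            daily_rows.append(
                {
                    "tag_id": tag,
                    "date": (start + pd.Timedelta(days=d)).date().isoformat(),
                    "true_lat": lats_true[d],
                    "true_lon": lons_true[d],
                    "true_percent_distance": pct_true[d],
                    "truncated": truncated,
                }
            )

        # emit fixes: linear interpolation between daily midday positions
        for d in range(n_days):
            n_fix = int(rng.poisson(trk.fixes_per_day_mean))
            if n_fix == 0:
                continue
            hours = np.sort(rng.uniform(0.0, 24.0, size=n_fix))
            for h in hours:
                t = d + h / 24.0  # days since start at 00:00
                # piecewise-linear path through the midday positions,
                # extrapolated (<= 12 h) beyond the first/last midday
                frac = t - 0.5
                if n_days == 1:
                    tlat, tlon = lats_true[0], lons_true[0]
                else:
                    i0 = int(np.clip(np.floor(frac), 0, n_days - 2))
                    w = frac - i0
                    tlat = (1 - w) * lats_true[i0] + w * lats_true[i0 + 1]
                    tlon = (1 - w) * lons_true[i0] + w * lons_true[i0 + 1]
                quality = classes[int(rng.choice(len(classes), p=probs))]
                sd_km = trk.error_sd_km.get(quality, 1.0)
                err_n = rng.normal(0.0, sd_km)
                err_e = rng.normal(0.0, sd_km)
                is_outlier = bool(rng.random() < trk.outlier_rate)
                if is_outlier:
                    mag = rng.uniform(*trk.outlier_km_range)
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    err_n += mag * np.sin(theta)
                    err_e += mag * np.cos(theta)
                flat = tlat + err_n / 110.6
                flon = tlon + err_e / _km_per_deg_lon(tlat)
                ts = start + pd.Timedelta(days=float(t))
                fix_rows.append(
                    {
                        "tag_id": tag,
                        "timestamp": ts.isoformat(),
                        "lat": round(flat, 6),
                        "lon": round(flon, 6),
                        "quality": quality,
                    }
                )
                truth_fix_rows.append(
                    {
                        "tag_id": tag,
                        "timestamp": ts.isoformat(),
                        "true_lat": tlat,
                        "true_lon": tlon,
                        "is_outlier": is_outlier,
                    }
                )

    fixes = pd.DataFrame(fix_rows, columns=["tag_id", "timestamp", "lat", "lon", "quality"])
    truth_daily = pd.DataFrame(
        daily_rows,
        columns=["tag_id", "date", "true_lat", "true_lon", "true_percent_distance", "truncated"],
    )
    truth_fixes = pd.DataFrame(
        truth_fix_rows, columns=["tag_id", "timestamp", "true_lat", "true_lon", "is_outlier"]
    )
    return fixes, truth_daily, truth_fixes


# ---------------------------------------------------------------------------
# time-at-temperature
# ---------------------------------------------------------------------------

def sample_true_temperatures(
    cfg: ScenarioConfig, sst: xr.DataArray, truth_daily: pd.DataFrame, step_hours: float = 2.0
) -> pd.DataFrame:
    """Occupied-temperature series per animal, sampled from SST at the true track."""
    start = pd.Timestamp(cfg.domain.start_date)
    rows = []
    lat_c, lon_c = sst.lat.values, sst.lon.values
    t_axis = (sst.time.values - np.datetime64(start)) / np.timedelta64(1, "D")
    for tag, grp in truth_daily.groupby("tag_id", sort=True):
        grp = grp.sort_values("date")
        lats = grp["true_lat"].to_numpy()
        lons = grp["true_lon"].to_numpy()
        n_days = len(grp)
        times_h = np.arange(0.0, n_days * 24.0, step_hours)
        for h in times_h:
            frac = np.clip(h / 24.0 - 0.5, 0.0, n_days - 1.0)
            i0 = int(np.floor(frac))
            i1 = min(i0 + 1, n_days - 1)
            w = frac - i0
            lat = (1 - w) * lats[i0] + w * lats[i1]
            lon = (1 - w) * lons[i0] + w * lons[i1]
            it = _nearest_index(t_axis, h / 24.0)
            iy = _nearest_index(lat_c, lat)
            ix = _nearest_index(lon_c, lon)
            rows.append(
                {
                    "tag_id": tag,
                    "timestamp": (start + pd.Timedelta(hours=float(h))).isoformat(),
                    "temp_c": float(sst.values[it, iy, ix]),
                }
            )
    return pd.DataFrame(rows, columns=["tag_id", "timestamp", "temp_c"])


def generate_tat(cfg: ScenarioConfig, true_temps: pd.DataFrame) -> pd.DataFrame:
    """Bin occupied-temperature series into 12-hour time-at-temperature records.

    Windows are anchored at 00:00 and 12:00 UTC (dawn/dusk at UTC-6, matching
    archival-tag summary periods).  Fractions use the standard tag bin
    boundaries and sum to 1 per record; empty windows are omitted and logged.
    """
    df = true_temps.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["window_start"] = df["timestamp"].dt.floor("12h")
    cols = tat_bin_columns()
    rows = []
    n_empty = 0
    for (tag, wstart), grp in df.groupby(["tag_id", "window_start"], sort=True):
        temps = grp["temp_c"].to_numpy()
        if len(temps) == 0:
            n_empty += 1
            continue
        counts, _ = np.histogram(temps, bins=TAT_BIN_EDGES)
        frac = counts / counts.sum()
        row = {"tag_id": tag, "window_start": wstart.isoformat()}
        row.update({c: frac[i] for i, c in enumerate(cols)})
        rows.append(row)
    if n_empty:
        log.info("omitted %d empty 12-h windows", n_empty)
    return pd.DataFrame(rows, columns=["tag_id", "window_start", *cols])


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_field(da: xr.DataArray, path) -> None:
    """Write a gridded field as CF-style netCDF (classic format)."""
    ds = da.to_dataset()
    ds.attrs["Conventions"] = "CF-1.8"
    ds.to_netcdf(path, engine="scipy")


def read_field(path, var: str | None = None) -> xr.DataArray:
    ds = xr.open_dataset(path, engine="scipy")
    name = var or next(iter(ds.data_vars))
    return ds[name].load()


# ---------------------------------------------------------------------------
# constructed sections (profile-level synthesis, no gridded field needed)
# ---------------------------------------------------------------------------

def synthetic_section(
    d_min_km: float = -250.0,
    width_km: float = 300.0,
    grid_km: float = 27.8,
    noise_sd_c: float = 0.0,
    seed: int = 0,
    south_gradient_c_per_km: float = 0.01,
    background_gradient_c_per_km: float = 0.0005,
    t_min_c: float = 20.0,
    rise_c: float = 6.0,
    half_length_km: float = 800.0,
    orientation: str = "meridional",
):
    """Animal-centric piecewise-linear front profile with known edges.

    A direct construction of the canonical section shape — warm on the
    equatorward far side, V-minimum at ``d_min_km``, linear frontal rise to
    the slope break at ``d_min_km + width_km``, weak background gradient
    beyond — used for edge-detector oracle tests where the true edge
    locations must be exact.  For ``orientation='zonal'`` the axis is
    mirrored (minimum inshore/east, break offshore/west).
    """
    from .sst_fields import FrontSection

    rng = np.random.default_rng(seed)
    d = np.arange(-half_length_km, half_length_km + grid_km / 2, grid_km)
    if not np.any(np.isclose(d, 0.0)):
        d = np.sort(np.append(d, 0.0))
    v = np.where(
        d < d_min_km,
        t_min_c + south_gradient_c_per_km * (d_min_km - d),
        np.where(
            d <= d_min_km + width_km,
            t_min_c + rise_c / width_km * (d - d_min_km),
            t_min_c + rise_c + background_gradient_c_per_km * (d - d_min_km - width_km),
        ),
    )
    v = v + rng.normal(0.0, noise_sd_c, size=len(d))
    if orientation == "zonal":
        d, v = -d[::-1], v[::-1]
    return FrontSection(
        tag_id="SYNTH",
        date="2011-09-05",
        anchor_lat=0.0,
        anchor_lon=-100.0,
        orientation=orientation,
        coords=d.copy(),
        distance_km=d,
        sst_c=v,
    )
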