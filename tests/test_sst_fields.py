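"""Compositing, long-term means, and animal-centric section extraction."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from thermofront import sst_fields
from thermofront.config import ScenarioConfig
from thermofront.geodesy import meridional_distance_km, zonal_distance_km
from thermofront.sst_fields import (
    composite_3day,
    composite_series,
    extract_section,
    long_term_mean,
    nearest_time_index,
)
from thermofront.synthetic import generate_sst_field


def small_field(values, lats=None, lons=None, start="2011-09-01"):
    values = np.asarray(values, dtype=float)
    nt, ny, nx = values.shape
    lats = np.linspace(-2, 2, ny) if lats is None else lats
    lons = np.linspace(-102, -98, nx) if lons is None else lons
    return xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={"time": pd.date_range(start, periods=nt), "lat": lats, "lon": lons},
        name="sst",
        attrs={"units": "degC"},
    )


class TestComposite:
    def test_identical_slices_unchanged(self):
        f = small_field(np.full((3, 4, 4), 25.0))
        c = composite_3day(f, "2011-09-02")
        assert np.allclose(c.values, 25.0)

    def test_mean_of_three(self):
        vals = np.stack([np.full((4, 4), v) for v in (20.0, 21.0, 22.0)])
        c = composite_3day(small_field(vals), "2011-09-02")
        assert np.allclose(c.values, 21.0)

    def test_masked_cell_uses_available_slices(self):
        """Cell masked on day 1 only: mean of 24 and 26 is 25."""
        vals = np.stack([np.full((4, 4), v) for v in (99.0, 24.0, 26.0)])
        vals[0, 1, 1] = np.nan
        c = composite_3day(small_field(vals), "2011-09-02")
        assert c.values[1, 1] == pytest.approx(25.0)
        # cells present in all three use all three
        assert c.values[0, 0] == pytest.approx((99 + 24 + 26) / 3)

    def test_masked_everywhere_stays_masked(self):
        vals = np.full((3, 4, 4), 25.0)
        vals[:, 2, 2] = np.nan
        c = composite_3day(small_field(vals), "2011-09-02")
        assert np.isnan(c.values[2, 2])

    def test_edge_uses_available_subset(self):
        vals = np.stack([np.full((4, 4), v) for v in (20.0, 22.0, 99.0)])
        c = composite_3day(small_field(vals), "2011-09-01")  # first day: 2 slices
        assert np.allclose(c.values, 21.0)

    def test_no_slices_raises(self):
        f = small_field(np.full((3, 4, 4), 25.0))
        with pytest.raises(ValueError):
            composite_3day(f, "2011-10-01")

    def test_series_matches_single_composites(self):
        rng = np.random.default_rng(1)
        f = small_field(rng.normal(25, 1, size=(6, 5, 5)))
        series = composite_series(f)
        for i, day in enumerate(pd.date_range("2011-09-01", periods=6)):
            single = composite_3day(f, day)
            assert np.allclose(series.isel(time=i).values, single.values)


class TestLongTermMean:
    def test_single_slice_is_itself(self):
        f = small_field(np.random.default_rng(0).normal(size=(1, 4, 4)) + 25)
        assert np.allclose(long_term_mean(f).values, f.isel(time=0).values)

    def test_alternating_mean(self):
        vals = np.stack([np.full((3, 3), 20.0 if i % 2 == 0 else 30.0) for i in range(6)])
        assert np.allclose(long_term_mean(small_field(vals)).values, 25.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(25, 2, size=(10, 4, 4))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        got = long_term_mean(small_field(vals)).values
        brute = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                col = vals[:, i, j]
                brute[i, j] = np.mean(col[~np.isnan(col)]) if (~np.isnan(col)).any() else np.nan
        assert np.allclose(got, brute, equal_nan=True, atol=1e-12)

    def test_empty_period_raises(self):
        f = small_field(np.full((3, 4, 4), 25.0))
        with pytest.raises(ValueError):
            long_term_mean(f, period=slice("2012-01-01", "2012-02-01"))


class TestNearestTime:
    def test_tie_goes_to_earlier(self):
        f = small_field(np.zeros((4, 3, 3)))
        # 12:00 on day boundary between day 1 (00:00) and day 2 (00:00)
        idx = nearest_time_index(f, "2011-09-01T12:00:00")
        assert idx == 0


class TestExtractSection:
    def test_constant_field_constant_section(self):
        f = small_field(np.full((1, 41, 41), 25.0),
                        lats=np.linspace(-5, 5, 41), lons=np.linspace(-105, -95, 41))
        for orient in ("meridional", "zonal"):
            s = extract_section(f.isel(time=0), 0.3, -100.2, orientation=orient,
                                half_length_km=300, min_span_km=100)
            assert np.allclose(s.sst_c, 25.0)
            assert s.distance_km[0] < 0 < s.distance_km[-1]
            assert np.all(np.diff(s.distance_km) > 0)

    def test_anchor_at_node_is_exact(self):
        rng = np.random.default_rng(3)
        lats = np.linspace(-5, 5, 21)
        lons = np.linspace(-105, -95, 21)
        f = small_field(rng.normal(25, 1, (1, 21, 21)), lats=lats, lons=lons)
        s = extract_section(f.isel(time=0), lats[10], lons[7], half_length_km=200, min_span_km=50)
        assert s.value_at(0.0) == f.values[0, 10, 7]

    def test_recovers_scenario_t_min(self):
        cfg = ScenarioConfig(seed=2)
        cfg.front.meander_amp_km = 0.0
        cfg.front.noise_sd_c = 0.0
        sst = generate_sst_field(cfg)
        s = extract_section(sst.isel(time=0), cfg.front.mean_lat + 1.0, -100.0)
        assert s.sst_c.min() == pytest.approx(cfg.front.t_min, abs=0.15)

    def test_offset_invariance(self):
        cfg = ScenarioConfig(seed=2)
        sst = generate_sst_field(cfg)
        s0 = extract_section(sst.isel(time=0), 1.5, -100.0)
        s3 = extract_section((sst + 3.0).isel(time=0), 1.5, -100.0)
        assert np.allclose(s3.sst_c, s0.sst_c + 3.0)
        assert np.allclose(s3.distance_km, s0.distance_km)

    def test_distance_axis_matches_geodesic_oracle(self):
        cfg = ScenarioConfig(seed=2)
        sst = generate_sst_field(cfg)
        anchor_lat, anchor_lon = 1.1, -100.05
        sm = extract_section(sst.isel(time=0), anchor_lat, anchor_lon, orientation="meridional")
        # meridional: sample distances equal signed meridian-arc distances
        expect = meridional_distance_km(anchor_lat, sm.coords)
        assert np.allclose(sm.distance_km, expect, atol=1e-6)
        sz = extract_section(sst.isel(time=0), anchor_lat, anchor_lon, orientation="zonal")
        expect_z = zonal_distance_km(anchor_lat, anchor_lon, sz.coords)
        assert np.allclose(sz.distance_km, expect_z, atol=1e-6)
        # zonal spacing scales with cos(latitude)
        step_z = np.median(np.diff(sz.distance_km))
        step_m = np.median(np.diff(sm.distance_km))
        assert step_z / step_m == pytest.approx(
            np.cos(np.radians(anchor_lat)) * 111.32 / 110.6, rel=5e-3
        )

    def test_masked_anchor_raises(self):
        vals = np.full((1, 21, 21), 25.0)
        vals[0, 10, 10] = np.nan
        f = small_field(vals, lats=np.linspace(-5, 5, 21), lons=np.linspace(-105, -95, 21))
        with pytest.raises(ValueError, match="anchor"):
            extract_section(f.isel(time=0), 0.0, -100.0, half_length_km=300, min_span_km=50)

    def test_short_section_flagged(self):
        f = small_field(np.full((1, 9, 9), 25.0),
                        lats=np.linspace(-1, 1, 9), lons=np.linspace(-101, -99, 9))
        s = extract_section(f.isel(time=0), 0.0, -100.0, half_length_km=800, min_span_km=300)
        assert "short_section" in s.flags

    def test_outside_domain_raises(self):
        f = small_field(np.full((1, 9, 9), 25.0))
        with pytest.raises(ValueError, match="outside"):
            extract_section(f.isel(time=0), 30.0, -100.0)
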