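"""Generator contracts: field structure, track modes, TAT binning, determinism."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from thermofront import synthetic
from thermofront.config import ScenarioConfig, TrackConfig
from thermofront.geodesy import meridional_distance_km
from thermofront.synthetic import (
    front_base_lat,
    generate_current_field,
    generate_sst_field,
    generate_tat,
    generate_tracks,
    true_percent_distance,
)
from thermofront.tat_analysis import tat_bin_columns


def quiet_cfg(**front_kw) -> ScenarioConfig:
    cfg = ScenarioConfig(seed=1)
    cfg.front.meander_amp_km = 0.0
    cfg.front.noise_sd_c = 0.0
    cfg.current.noise_sd_ms = 0.0
    for k, v in front_kw.items():
        setattr(cfg.front, k, v)
    cfg.validate()
    return cfg


class TestSSTField:
    def test_zero_meander_minimum_at_mean_front_latitude(self):
        cfg = quiet_cfg(t_min=20.0, t_north=26.0, width_km=300.0)
        sst = generate_sst_field(cfg)
        lats = sst.lat.values
        imin = sst.isel(time=0).values.argmin(axis=0)
        target = np.abs(lats - cfg.front.mean_lat).argmin()
        assert (imin == target).all()
        # 6 degC rise over the 300 km frontal width
        col = sst.isel(time=0, lon=5).values
        lat_break = cfg.front.mean_lat + 300.0 / 110.6
        v_break = np.interp(lat_break, lats, col)
        # interpolating across the slope-break kink rounds the corner by up
        # to half a cell times the slope change
        assert v_break == pytest.approx(26.0, abs=0.3)
        north = col[lats > lat_break + 0.3]
        assert np.all(north > 26.0 - 1e-9)

    def test_meander_sine_symmetry(self):
        cfg = ScenarioConfig(seed=1)
        cfg.front.meander_amp_km = 150.0
        cfg.front.meander_wavelength_km = 1000.0
        lon0 = cfg.domain.lon_min + 2.0
        # half a wavelength east in km
        dlon = 500.0 / (111.32 * np.cos(np.radians(cfg.front.mean_lat)))
        b0 = front_base_lat(cfg, lon0, 3.0)
        b1 = front_base_lat(cfg, lon0 + dlon, 3.0)
        # sine flips sign at lambda/2: separation is twice the displacement
        sep_km = abs(meridional_distance_km(b0, b1))
        disp_km = abs(meridional_distance_km(cfg.front.mean_lat, b0))
        assert sep_km == pytest.approx(2 * disp_km, rel=1e-3)

    def test_grid_minimum_equals_t_min_within_cell(self):
        cfg = quiet_cfg()
        cfg.front.meander_amp_km = 120.0
        sst = generate_sst_field(cfg)
        # brute-force scan of the emitted grid
        grid_km = cfg.domain.grid_deg * 110.6
        worst_cell_err = 0.5 * grid_km * cfg.front.south_gradient_c_per_100km / 100.0 + 0.05
        assert float(sst.min()) == pytest.approx(cfg.front.t_min, abs=max(worst_cell_err, 0.2))
        assert float(sst.min()) >= cfg.front.t_min - 1e-9

    def test_domain_too_small_raises(self):
        cfg = ScenarioConfig(seed=1)
        cfg.domain.lat_max = 2.0  # cannot contain front + meander + width
        with pytest.raises(ValueError, match="lat_max"):
            cfg.validate()

    def test_cf_metadata(self):
        sst = generate_sst_field(quiet_cfg())
        assert sst.attrs["units"] == "degC"
        assert sst.lat.attrs["standard_name"] == "latitude"
        assert list(sst.dims) == ["time", "lat", "lon"]


class TestCurrentField:
    def test_core_speed_at_front_base(self):
        cfg = quiet_cfg()
        cfg.current.core_westward_ms = 1.0
        u = generate_current_field(cfg)
        iy = np.abs(u.lat.values - cfg.front.mean_lat).argmin()
        core = u.isel(time=0, lat=iy).values
        assert np.allclose(core, -1.0, atol=0.01)

    def test_gaussian_tail_decays_to_zero(self):
        cfg = quiet_cfg()
        u = generate_current_field(cfg)
        far = u.sel(lat=cfg.domain.lat_max, method="nearest").values
        assert np.all(np.abs(far) < 0.01)

    def test_noise_sd_recovered(self):
        cfg = ScenarioConfig(seed=9)
        cfg.front.meander_amp_km = 0.0
        cfg.current.noise_sd_ms = 0.1
        u = generate_current_field(cfg)
        # far from the core the signal is ~0, samples are pure noise
        far = u.where(abs(u.lat - cfg.front.mean_lat) > 4.0, drop=True).values.ravel()
        assert len(far) > 10_000
        assert np.std(far) == pytest.approx(0.1, rel=0.1)


class TestTracks:
    def test_passive_drift_daily_displacement(self):
        """u = -1 m/s at the equator moves a drifter -86.4 km per day."""
        cfg = quiet_cfg()
        cfg.front.mean_lat = 0.0
        cfg.track = TrackConfig(
            n_animals=1, duration_days=4, mode="passive", fixes_per_day_mean=1.0,
            error_sd_km={c: 0.0 for c in "3210AB"},
            quality_probs={"3": 1.0, "2": 0.0, "1": 0.0, "0": 0.0, "A": 0.0, "B": 0.0},
        )
        sst = generate_sst_field(cfg)
        u = generate_current_field(cfg)
        u = xr.full_like(u, -1.0)  # uniform 1 m/s westward
        _, truth, _ = generate_tracks(cfg, sst, u)
        lat0 = truth["true_lat"].iloc[0]
        from thermofront.geodesy import zonal_distance_km

        for i in range(len(truth) - 1):
            d = zonal_distance_km(lat0, truth["true_lon"].iloc[i], truth["true_lon"].iloc[i + 1])
            # 86400 s at 1 m/s, scaled by cos(lat) consistency of the geodesic
            assert d == pytest.approx(-86.4, abs=0.15)

    def test_front_biased_tracks_hold_target_percent_distance(self, quiet_front_scenario):
        """Closed loop: detection on the same field recovers the 50 % target."""
        from thermofront import front_metrics, sst_fields

        cfg = quiet_front_scenario
        cfg.track.target_pct_mean = 50.0
        cfg.track.target_pct_sd = 0.0
        cfg.track.meridional_noise_km = 0.0
        sst = generate_sst_field(cfg)
        u = generate_current_field(cfg)
        _, truth, _ = generate_tracks(cfg, sst, u)
        assert np.allclose(truth["true_percent_distance"], 50.0, atol=1.0)
        comp = sst_fields.composite_series(sst)
        grid_pct = 100.0 * cfg.domain.grid_deg * 110.6 / cfg.front.width_km  # one cell
        for _, row in truth.iloc[:6].iterrows():
            it = sst_fields.nearest_time_index(comp, row["date"])
            sec = sst_fields.extract_section(
                comp.isel(time=it), row["true_lat"], row["true_lon"]
            )
            rec = front_metrics.percent_distance(front_metrics.detect_front(sec))
            assert rec.percent_distance == pytest.approx(50.0, abs=grid_pct)

    def test_zero_error_fixes_equal_true_positions(self, quiet_front_scenario):
        cfg = quiet_front_scenario
        sst = generate_sst_field(cfg)
        u = generate_current_field(cfg)
        fixes, _, truth_fixes = generate_tracks(cfg, sst, u)
        assert len(fixes) == len(truth_fixes)
        assert np.allclose(fixes["lat"], truth_fixes["true_lat"], atol=1e-6)
        assert np.allclose(fixes["lon"], truth_fixes["true_lon"], atol=1e-6)
        assert (fixes["quality"] == "3").all()

    def test_true_percent_distance_matches_geometry(self):
        cfg = quiet_cfg()
        lat = cfg.front.mean_lat + 150.0 / 110.6
        pct = true_percent_distance(cfg, lat, -100.0, 0.0)
        assert pct == pytest.approx(50.0, abs=0.2)


class TestTAT:
    def _temps(self, values, start="2011-09-01T00:00:00"):
        times = pd.date_range(start, periods=len(values), freq="30min")
        return pd.DataFrame({"tag_id": "T", "timestamp": times.astype(str), "temp_c": values})

    def test_constant_occupancy_single_bin(self):
        tat = generate_tat(ScenarioConfig(), self._temps([25.0] * 24))
        cols = tat_bin_columns()
        assert tat[cols].iloc[0]["frac_24_26"] == 1.0
        assert tat[cols].iloc[0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_half_and_half(self):
        vals = [19.0] * 12 + [27.0] * 12
        tat = generate_tat(ScenarioConfig(), self._temps(vals))
        row = tat.iloc[0]
        assert row["frac_18_20"] == 0.5
        assert row["frac_26_28"] == 0.5

    def test_uniform_occupancy_proportional_to_bin_widths(self):
        # uniform over [0, 33): fractions proportional to bin widths
        vals = np.arange(0.0025, 33.0, 0.005)
        times = pd.date_range("2011-09-01", periods=len(vals), freq="s")
        df = pd.DataFrame({"tag_id": "T", "timestamp": times.astype(str), "temp_c": vals})
        tat = generate_tat(ScenarioConfig(), df)
        row = tat.iloc[0]
        assert row["frac_0_5"] == pytest.approx(5 / 33, abs=1e-9)
        assert row["frac_18_20"] == pytest.approx(2 / 33, abs=1e-9)
        assert row["frac_gt_30"] == pytest.approx(3 / 33, abs=1e-9)

    def test_windows_anchored_at_00_and_12_utc(self):
        times = ["2011-09-01T06:00:00", "2011-09-01T18:00:00"]
        df = pd.DataFrame({"tag_id": "T", "timestamp": times, "temp_c": [25.0, 19.0]})
        tat = generate_tat(ScenarioConfig(), df)
        assert list(tat["window_start"]) == ["2011-09-01T00:00:00", "2011-09-01T12:00:00"]


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg_a = ScenarioConfig(seed=5)
        cfg_a.track.n_animals = 2
        cfg_a.track.duration_days = 5
        cfg_b = ScenarioConfig(seed=5)
        cfg_b.track.n_animals = 2
        cfg_b.track.duration_days = 5
        sst_a, sst_b = generate_sst_field(cfg_a), generate_sst_field(cfg_b)
        assert (sst_a.values == sst_b.values).all()
        u_a, u_b = generate_current_field(cfg_a), generate_current_field(cfg_b)
        assert (u_a.values == u_b.values).all()
        fx_a, td_a, tf_a = generate_tracks(cfg_a, sst_a, u_a)
        fx_b, td_b, tf_b = generate_tracks(cfg_b, sst_b, u_b)
        pd.testing.assert_frame_equal(fx_a, fx_b)
        pd.testing.assert_frame_equal(td_a, td_b)
        pd.testing.assert_frame_equal(tf_a, tf_b)

    def test_different_seed_differs(self):
        a = generate_sst_field(ScenarioConfig(seed=1))
        b = generate_sst_field(ScenarioConfig(seed=2))
        assert not (a.values == b.values).all()
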