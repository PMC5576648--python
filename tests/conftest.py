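"""Shared fixtures: constructed SST sections and small synthetic scenarios."""

from __future__ import annotations

import pytest

from thermofront.sst_fields import FrontSection
from thermofront.synthetic import synthetic_section


def piecewise_section(
    d_min: float = -250.0,
    width: float = 300.0,
    grid_km: float = 27.8,
    noise_sd: float = 0.0,
    seed: int = 0,
    orientation: str = "meridional",
) -> FrontSection:
    """Animal-centric piecewise-linear front profile with known edges."""
    return synthetic_section(
        d_min_km=d_min,
        width_km=width,
        grid_km=grid_km,
        noise_sd_c=noise_sd,
        seed=seed,
        orientation=orientation,
    )


@pytest.fixture
def quiet_front_scenario():
    """Small noise-free equatorial scenario with a non-meandering front."""
    from thermofront.config import ScenarioConfig, TrackConfig

    cfg = ScenarioConfig(seed=11)
    cfg.front.meander_amp_km = 0.0
    cfg.front.noise_sd_c = 0.0
    cfg.current.noise_sd_ms = 0.0
    cfg.track = TrackConfig(
        n_animals=2,
        duration_days=6,
        mode="front-biased",
        fixes_per_day_mean=1.0,
        error_sd_km={c: 0.0 for c in "3210AB"},
        quality_probs={"3": 1.0, "2": 0.0, "1": 0.0, "0": 0.0, "A": 0.0, "B": 0.0},
    )
    cfg.validate()
    return cfg
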