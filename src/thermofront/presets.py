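"""Ready-made scenario presets.

Each returns a fresh :class:`ScenarioConfig`; callers may adjust sizes but
the physical settings are fixed scenario definitions:

* ``demo`` — the bundled end-to-end demonstration: a meandering equatorial
  front with front-biased animals, Argos-like errors, currents and TAT.
* ``passive_drift`` — animals advected purely by a steady westward jet
  (no meander, no noise, exact fixes): movement and currents must agree.
* ``independent_motion`` — unbiased random walkers over the same ocean:
  movement and currents must not agree.
* ``outlier_tracks`` — front-biased animals whose fix stream includes gross
  position failures, for filter performance tests.
* ``coastal`` — a coastal-upwelling plume with zonal sections.
"""

from __future__ import annotations

from .config import DomainConfig, FrontConfig, ScenarioConfig, TrackConfig

_EXACT_FIX = {
    "error_sd_km": {c: 0.0 for c in "3210AB"},
    "quality_probs": {"3": 1.0, "2": 0.0, "1": 0.0, "0": 0.0, "A": 0.0, "B": 0.0},
}


def demo(seed: int = 42) -> ScenarioConfig:
    cfg = ScenarioConfig(seed=seed)
    cfg.track.n_animals = 8
    cfg.track.duration_days = 28
    cfg.validate()
    return cfg


def passive_drift(seed: int = 0, n_animals: int = 25, duration_days: int = 25) -> ScenarioConfig:
    cfg = ScenarioConfig(seed=seed)
    cfg.front.meander_amp_km = 0.0
    cfg.front.noise_sd_c = 0.0
    cfg.current.noise_sd_ms = 0.0
    cfg.track = TrackConfig(
        n_animals=n_animals,
        duration_days=duration_days,
        mode="passive",
        fixes_per_day_mean=1.0,
        **_EXACT_FIX,
    )
    cfg.validate()
    return cfg


def independent_motion(seed: int = 0, n_animals: int = 50, duration_days: int = 12) -> ScenarioConfig:
    cfg = ScenarioConfig(seed=seed)
    cfg.track = TrackConfig(
        n_animals=n_animals,
        duration_days=duration_days,
        mode="independent",
        fixes_per_day_mean=1.0,
        **_EXACT_FIX,
    )
    cfg.validate()
    return cfg


def outlier_tracks(seed: int = 0, n_animals: int = 10, duration_days: int = 25) -> ScenarioConfig:
    cfg = ScenarioConfig(seed=seed)
    cfg.track.n_animals = n_animals
    cfg.track.duration_days = duration_days
    cfg.track.outlier_rate = 0.1
    cfg.validate()
    return cfg


def coastal(seed: int = 0) -> ScenarioConfig:
    cfg = ScenarioConfig(
        seed=seed,
        orientation="coastal",
        domain=DomainConfig(lat_min=-10.0, lat_max=0.0, lon_min=-92.0, lon_max=-80.0),
        front=FrontConfig(
            t_min=17.0,
            t_north=23.0,
            width_km=250.0,
            meander_amp_km=60.0,
            meander_wavelength_km=600.0,
        ),
    )
    cfg.track.n_animals = 4
    cfg.track.duration_days = 28
    cfg.validate()
    return cfg


PRESETS = {
    "demo": demo,
    "passive-drift": passive_drift,
    "independent-motion": independent_motion,
    "outlier-tracks": outlier_tracks,
    "coastal": coastal,
}
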