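"""Scenario and run configuration.

Plain dataclasses with explicit validation; round-trips through YAML so a
scenario or analysis run is fully described by one small text file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B")

#: Per-class 1-sigma position error, km.  Argos location classes span
#: accuracies from a few hundred metres (class 3) to many kilometres (class B).
DEFAULT_ERROR_SD_KM = {"3": 0.25, "2": 0.5, "1": 1.5, "0": 5.0, "A": 5.0, "B": 10.0}

#: Default mix of location classes for a towed-tag equatorial deployment.
DEFAULT_QUALITY_PROBS = {"3": 0.15, "2": 0.25, "1": 0.2, "0": 0.1, "A": 0.15, "B": 0.15}


@dataclass
class DomainConfig:
    """Regular lat/lon grid and daily time axis for the synthetic ocean."""

    lat_min: float = -8.0
    lat_max: float = 8.0
    lon_min: float = -120.0
    lon_max: float = -90.0
    grid_deg: float = 0.25
    n_days: int = 30
    start_date: str = "2011-09-01"

    def validate(self) -> None:
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("domain bounds must satisfy min < max")
        if self.grid_deg <= 0:
            raise ValueError("grid_deg must be positive")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")


@dataclass
class FrontConfig:
    """Piecewise-linear upwelling front with a sinusoidal meander.

    The meridional profile of each column runs, south to north: a rise toward
    the south at ``south_gradient_c_per_100km`` (warm water beyond the
    upwelling's reach), the temperature minimum at the meandering base
    latitude, a linear rise of ``t_north - t_min`` over ``width_km`` (the
    front proper), then a weak background gradient.  The meander displaces the
    base latitude by ``A sin(2*pi*x/lambda - 2*pi*t/P)``; an optional second
    harmonic adds vortex-like distortion.
    """

    t_min: float = 20.0
    t_north: float = 26.0
    width_km: float = 300.0
    mean_lat: float = 1.0
    meander_amp_km: float = 150.0
    meander_wavelength_km: float = 1000.0
    meander_period_days: float = 25.0
    second_harmonic_frac: float = 0.0
    south_gradient_c_per_100km: float = 1.0
    background_gradient_c_per_1000km: float = 0.5
    noise_sd_c: float = 0.1

    def validate(self) -> None:
        if self.width_km <= 0:
            raise ValueError("front width_km must be > 0")
        if self.meander_amp_km < 0:
            raise ValueError("meander_amp_km must be >= 0")
        if self.t_north <= self.t_min:
            raise ValueError("t_north must exceed t_min")
        if self.meander_wavelength_km <= 0 or self.meander_period_days <= 0:
            raise ValueError("meander wavelength and period must be positive")
        if self.noise_sd_c < 0:
            raise ValueError("noise_sd_c must be >= 0")


@dataclass
class PlumeConfig:
    """Coastal-upwelling variant (zonal analysis off an eastern boundary)."""

    axis_lat: float = -5.0
    coast_lon: float = -81.0
    offshore_decay_km: float = 200.0
    warming_c_per_month: float = 0.5


@dataclass
class CurrentConfig:
    """Zonal surface current: westward jet on the front base, Gaussian decay."""

    core_westward_ms: float = 1.0  # positive number = westward core speed
    meridional_scale_km: float = 200.0
    noise_sd_ms: float = 0.1
    grid_deg: float = 1.0 / 3.0
    time_step_days: int = 5

    def validate(self) -> None:
        if self.meridional_scale_km <= 0:
            raise ValueError("meridional_scale_km must be > 0")
        if self.noise_sd_ms < 0:
            raise ValueError("noise_sd_ms must be >= 0")


@dataclass
class TrackConfig:
    """Animal movement and Argos-like fix emission."""

    n_animals: int = 27
    duration_days: int = 63
    mode: str = "front-biased"  # passive | front-biased | independent
    target_pct_mean: float = 75.0
    target_pct_sd: float = 15.0
    zonal_step_sd_km: float = 20.0
    meridional_noise_km: float = 5.0
    relax_rate: float = 1.0
    fixes_per_day_mean: float = 4.0
    error_sd_km: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ERROR_SD_KM))
    quality_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_QUALITY_PROBS))
    outlier_rate: float = 0.0
    outlier_km_range: tuple[float, float] = (250.0, 600.0)

    def validate(self) -> None:
        if self.mode not in ("passive", "front-biased", "independent"):
            raise ValueError(f"unknown movement mode {self.mode!r}")
        if self.n_animals < 1 or self.duration_days < 1:
            raise ValueError("n_animals and duration_days must be >= 1")
        if set(self.quality_probs) - set(ARGOS_CLASSES):
            raise ValueError("quality_probs keys must be Argos classes 3,2,1,0,A,B")
        if abs(sum(self.quality_probs.values()) - 1.0) > 1e-9:
            raise ValueError("quality_probs must sum to 1")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")


@dataclass
class ScenarioConfig:
    """Full synthetic scenario: ocean fields + animal tracks + tag records."""

    domain: DomainConfig = field(default_factory=DomainConfig)
    front: FrontConfig = field(default_factory=FrontConfig)
    plume: PlumeConfig = field(default_factory=PlumeConfig)
    current: CurrentConfig = field(default_factory=CurrentConfig)
    track: TrackConfig = field(default_factory=TrackConfig)
    orientation: str = "equatorial"  # equatorial (meridional sections) | coastal (zonal)
    seed: int = 0

    def validate(self) -> None:
        self.domain.validate()
        self.front.validate()
        self.current.validate()
        self.track.validate()
        if self.orientation not in ("equatorial", "coastal"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.orientation == "equatorial":
            amp_deg = self.meander_amp_deg()
            width_deg = self.front.width_km / 110.6
            south_need = self.front.mean_lat - amp_deg - 1.0
            north_need = self.front.mean_lat + amp_deg + width_deg + 1.0
            if self.domain.lat_min > south_need:
                raise ValueError(
                    f"domain lat_min={self.domain.lat_min} too high: front base can reach "
                    f"{self.front.mean_lat - amp_deg:.2f} deg; need lat_min <= {south_need:.2f}"
                )
            if self.domain.lat_max < north_need:
                raise ValueError(
                    f"domain lat_max={self.domain.lat_max} too low: front top can reach "
                    f"{north_need:.2f} deg; need lat_max >= {north_need:.2f}"
                )

    def meander_amp_deg(self) -> float:
        return self.front.meander_amp_km / 110.6


def _to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    return obj


def scenario_to_dict(cfg: ScenarioConfig) -> dict:
    return _to_dict(cfg)


def scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    kwargs: dict[str, Any] = {}
    for name, cls in (
        ("domain", DomainConfig),
        ("front", FrontConfig),
        ("plume", PlumeConfig),
        ("current", CurrentConfig),
        ("track", TrackConfig),
    ):
        if name in d:
            kwargs[name] = cls(**d.pop(name))
    if "track" in kwargs and isinstance(kwargs["track"].outlier_km_range, list):
        kwargs["track"].outlier_km_range = tuple(kwargs["track"].outlier_km_range)
    kwargs.update(d)
    cfg = ScenarioConfig(**kwargs)
    cfg.validate()
    return cfg


def save_scenario(cfg: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(cfg), fh, sort_keys=True)


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
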