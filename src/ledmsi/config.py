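"""Run configuration: schema-validated YAML describing one protocol run.

A config names a protocol and supplies band set, geometry, sensor, capture
plan, fixture and seed.  Unknown keys anywhere in the document are
rejected before any computation, and the master seed fully determines all
stochastic outputs of the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bands import SpectralBand, default_band_set
from .errors import ConfigError
from .optics_sim import DEFAULT_DIFFUSE_FRACTION, Geometry, SensorModel

SCHEMA_VERSION = 1

PROTOCOLS = ("evenness", "sensitivity", "consistency", "timelapse-pca", "analyte")

_TOP_KEYS = {"schema_version", "protocol", "seed", "out", "diffuse_fraction",
             "bands", "geometry", "sensor", "plan", "fixture"}
_GEOMETRY_KEYS = {"dome_radius_cm", "rop_radius_cm", "led_distance_cm",
                  "led_angles_deg", "pixel_pitch_mm"}
_SENSOR_KEYS = {"dark_offset", "read_noise_sd", "shot_noise_gain", "gain",
                "flicker_sd"}
_BAND_KEYS = {"name", "peak_nm", "fwhm_nm", "duty"}
_PLAN_KEYS = {"bands", "n_sets", "interval_s", "pca_per_set"}
_FIXTURE_KEYS = {"name", "params"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class PlanConfig:
    bands: list[str] = field(default_factory=lambda: ["525"])
    n_sets: int = 1
    interval_s: float = 0.0
    pca_per_set: bool = False


@dataclass
class FixtureConfig:
    name: str = "pink_disk"
    params: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Validated description of one experiment run."""

    protocol: str
    seed: int = 0
    out: str = "runs/out"
    diffuse_fraction: float = DEFAULT_DIFFUSE_FRACTION
    bands: list[SpectralBand] = field(default_factory=default_band_set)
    geometry: Geometry = field(default_factory=Geometry)
    sensor: SensorModel = field(default_factory=SensorModel)
    plan: PlanConfig = field(default_factory=PlanConfig)
    fixture: FixtureConfig = field(default_factory=FixtureConfig)

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise ConfigError(
                f"unknown protocol {self.protocol!r}; known: {PROTOCOLS}")
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ConfigError("band names must be unique")

    def band_by_name(self, name: str) -> SpectralBand:
        for b in self.bands:
            if b.name == name:
                return b
        raise ConfigError(f"band {name!r} not in the configured band set")

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "protocol": self.protocol,
            "seed": self.seed,
            "out": self.out,
            "diffuse_fraction": self.diffuse_fraction,
            "bands": [{"name": b.name, "peak_nm": b.peak_nm,
                       "fwhm_nm": b.fwhm_nm, "duty": b.duty}
                      for b in self.bands],
            "geometry": {
                "dome_radius_cm": self.geometry.dome_radius_cm,
                "rop_radius_cm": self.geometry.rop_radius_cm,
                "led_distance_cm": self.geometry.led_distance_cm,
                "led_angles_deg": list(self.geometry.led_angles_deg),
                "pixel_pitch_mm": self.geometry.pixel_pitch_mm,
            },
            "sensor": {k: getattr(self.sensor, k) for k in sorted(_SENSOR_KEYS)},
            "plan": vars(self.plan).copy(),
            "fixture": {"name": self.fixture.name,
                        "params": dict(self.fixture.params)},
        }


def config_from_dict(doc: dict) -> RunConfig:
    """Build and validate a RunConfig from a parsed YAML/JSON mapping."""
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    _check_keys(doc, _TOP_KEYS, "config root")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")
    if "protocol" not in doc:
        raise ConfigError("config must name a protocol")

    kwargs: dict = {"protocol": doc["protocol"]}
    for key in ("seed", "out", "diffuse_fraction"):
        if key in doc:
            kwargs[key] = doc[key]
    try:
        if "bands" in doc:
            bands = []
            for b in doc["bands"]:
                _check_keys(b, _BAND_KEYS, "band entry")
                bands.append(SpectralBand(**b))
            kwargs["bands"] = bands
        if "geometry" in doc:
            _check_keys(doc["geometry"], _GEOMETRY_KEYS, "geometry")
            kwargs["geometry"] = Geometry(**doc["geometry"])
        if "sensor" in doc:
            _check_keys(doc["sensor"], _SENSOR_KEYS, "sensor")
            kwargs["sensor"] = SensorModel(**doc["sensor"])
        if "plan" in doc:
            _check_keys(doc["plan"], _PLAN_KEYS, "plan")
            kwargs["plan"] = PlanConfig(**doc["plan"])
        if "fixture" in doc:
            _check_keys(doc["fixture"], _FIXTURE_KEYS, "fixture")
            kwargs["fixture"] = FixtureConfig(**doc["fixture"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config value: {exc}") from exc
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration file."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(doc)
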