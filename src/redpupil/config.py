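"""Structured run configuration (YAML) shared by all CLI entry points.

Schema (all sections optional; missing keys take the library defaults)::

    seed: 0
    simulator:
      band: far_red            # or full_visible
      blink_times_s: [2.0]
      blink_duration_s: 0.15
      eye:       {melanin_load: 2.5, noise_sd: 3.0, ...}   # SpectralEyeParams
      dynamics:  {baseline_diameter_px: 60, ...}           # PupilDynamicsParams
      protocol:  {frame_rate_hz: 60, ...}                  # PLRProtocol
    detection:   {downscale: 1, ...}                       # DetectionConfig
    analysis:
      target_rate_hz: 30.0
      max_lag_s: 0.5
      spike_threshold: 0.2

Every run writes its fully-resolved configuration next to its outputs so the
provenance of any result file is recoverable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segmentation import DetectionConfig
from .simulate import FAR_RED, FULL_VISIBLE, PLRProtocol, PupilDynamicsParams, SpectralEyeParams

__all__ = ["ConfigError", "AnalysisConfig", "SimulatorConfig", "RunConfig", "load_config", "dump_resolved_config"]

_BANDS = {"far_red": FAR_RED, "full_visible": FULL_VISIBLE}


class ConfigError(ValueError):
    """Malformed configuration; the message names the offending key."""


def _build(cls, section: dict, where: str):
    if not isinstance(section, dict):
        raise ConfigError(f"config section '{where}' must be a mapping")
    valid = {f.name for f in dataclasses.fields(cls)}
    for key in section:
        if key not in valid:
            raise ConfigError(f"unknown key '{where}.{key}'")
    coerced = {}
    for key, value in section.items():
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{where}': {exc}") from exc


@dataclass(frozen=True)
class AnalysisConfig:
    target_rate_hz: float = 30.0
    max_lag_s: float = 0.5
    spike_threshold: float = 0.2


@dataclass(frozen=True)
class SimulatorConfig:
    eye: SpectralEyeParams = field(default_factory=SpectralEyeParams)
    dynamics: PupilDynamicsParams = field(default_factory=PupilDynamicsParams)
    protocol: PLRProtocol = field(default_factory=PLRProtocol)
    band: str = "far_red"
    blink_times_s: tuple[float, ...] = ()
    blink_duration_s: float = 0.15

    def spectral_band(self):
        if self.band not in _BANDS:
            raise ConfigError(f"unknown key 'simulator.band' value {self.band!r}; choose one of {sorted(_BANDS)}")
        return _BANDS[self.band]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; ``None`` gives the all-defaults configuration."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")
    known = {"seed", "simulator", "detection", "analysis"}
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown key '{key}'")
    sim_raw = dict(raw.get("simulator", {}))
    if not isinstance(sim_raw, dict):
        raise ConfigError("config section 'simulator' must be a mapping")
    sim_kwargs = {}
    for sub, cls in (("eye", SpectralEyeParams), ("dynamics", PupilDynamicsParams), ("protocol", PLRProtocol)):
        if sub in sim_raw:
            sim_kwargs[sub] = _build(cls, sim_raw.pop(sub), f"simulator.{sub}")
    simulator = _build(SimulatorConfig, {**sim_raw, **{k: v for k, v in sim_kwargs.items()}}, "simulator")
    simulator.spectral_band()  # validate band name early
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("unknown or invalid key 'seed': must be an integer")
    return RunConfig(
        seed=seed,
        simulator=simulator,
        detection=_build(DetectionConfig, raw.get("detection", {}), "detection"),
        analysis=_build(AnalysisConfig, raw.get("analysis", {}), "analysis"),
    )


def dump_resolved_config(config: RunConfig, path: str | Path) -> Path:
    """Write the fully-resolved configuration as YAML (run provenance)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        return obj

    path.write_text(yaml.safe_dump(encode(config), sort_keys=False))
    return path
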