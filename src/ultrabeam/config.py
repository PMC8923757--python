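"""Run configuration: pydantic-validated YAML with strict unknown-key checks.

Every block mirrors a pipeline stage; every default is visible in the model
definitions below and echoed (fully resolved) into the JSON provenance
sidecar written next to each artifact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .array_model import (
    ArrayGeometry,
    Phantom,
    Pulse,
    make_cyst_phantom,
    make_linear_array,
)
from .imaging import ImageGrid

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised with every schema violation listed at once."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    num_elements: int = 64
    pitch_mm: float = 0.154
    center_frequency: float = 5e6
    sampling_frequency: float = 40e6
    sound_speed: float = 1540.0

    def build(self) -> ArrayGeometry:
        return make_linear_array(
            self.num_elements,
            self.pitch_mm,
            self.center_frequency,
            self.sampling_frequency,
            self.sound_speed,
        )


class PulseConfig(_Strict):
    center_frequency: Optional[float] = None  # defaults to geometry's
    fractional_bandwidth: float = 0.6
    duration_cycles: float = 2.5

    def build(self, geometry: ArrayGeometry) -> Pulse:
        fc = self.center_frequency or geometry.center_frequency
        return Pulse(fc, self.fractional_bandwidth, self.duration_cycles)


class ScattererConfig(_Strict):
    x_mm: float
    z_mm: float
    amplitude: float = 1.0


class PhantomConfig(_Strict):
    cyst_center_mm: Optional[tuple[float, float]] = (0.0, 20.0)
    cyst_radius_mm: float = 2.0
    field_extent_mm: tuple[tuple[float, float], tuple[float, float]] = (
        (-6.0, 6.0),
        (14.0, 26.0),
    )
    speckle_density: float = 3.0
    scatterers: list[ScattererConfig] = Field(default_factory=list)

    def build(self, seed: int) -> Phantom:
        extra = (
            np.array([[s.x_mm, s.z_mm, s.amplitude] for s in self.scatterers])
            if self.scatterers
            else None
        )
        if self.cyst_center_mm is None:
            if extra is None:
                raise ConfigError("phantom: no cyst and no explicit scatterers")
            return Phantom(scatterers=extra)
        return make_cyst_phantom(
            tuple(self.cyst_center_mm),
            self.cyst_radius_mm,
            tuple(tuple(p) for p in self.field_extent_mm),
            self.speckle_density,
            seed=seed,
            extra_scatterers=extra,
        )


class BeamformerConfig(_Strict):
    method: Literal["DAS", "SCB", "ISCB", "RLS", "SER"] = "ISCB"
    subarray_length: Optional[int] = None
    temporal_halfwidth: Optional[int] = None
    loading_factor: Optional[float] = None
    tau: Optional[float] = None
    threshold_factor: Optional[float] = None
    forgetting_factor: Optional[float] = None
    init_delta: Optional[float] = None
    step_schedule: Optional[float] = None

    def params(self) -> dict:
        out = self.model_dump(exclude={"method"}, exclude_none=True)
        return out


class GridConfig(_Strict):
    x_mm: tuple[float, float, int] = (-5.0, 5.0, 41)
    z_mm: tuple[float, float, int] = (16.0, 24.0, 33)

    def build(self) -> ImageGrid:
        return ImageGrid(
            np.linspace(*self.x_mm[:2], int(self.x_mm[2])),
            np.linspace(*self.z_mm[:2], int(self.z_mm[2])),
        )


class MetricsConfig(_Strict):
    dynamic_range: float = 60.0
    background_annulus_mm: tuple[float, float] = (3.0, 4.5)


class BenchmarkConfig(_Strict):
    methods: list[Literal["DAS", "SCB", "ISCB", "RLS", "SER"]] = Field(
        default_factory=lambda: ["DAS", "SCB", "ISCB"]
    )
    n_seeds: int = 5


class RunConfig(_Strict):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    pulse: PulseConfig = Field(default_factory=PulseConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    beamformer: BeamformerConfig = Field(default_factory=BeamformerConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    benchmark: BenchmarkConfig = Field(default_factory=BenchmarkConfig)
    noise_db: float = -30.0
    seed: int = 0

    def resolved(self) -> dict:
        """Fully-resolved config (defaults included) for provenance sidecars."""
        return json.loads(self.model_dump_json())

    def write_sidecar(self, artifact_path) -> None:
        from . import __version__

        sidecar = Path(str(artifact_path) + ".json")
        payload = {
            "config": self.resolved(),
            "package": "ultrabeam",
            "version": __version__,
            "seed": self.seed,
        }
        sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _apply_overrides(raw: dict, overrides: list[str]) -> dict:
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not of the form key.path=value")
        key, value = item.split("=", 1)
        node = raw
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = yaml.safe_load(value)
    return raw


def load_config(path=None, overrides: list[str] | None = None) -> RunConfig:
    """Load and validate a YAML config; list all schema errors at once."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    if overrides:
        raw = _apply_overrides(raw, list(overrides))
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            "invalid configuration:\n" + "\n".join(lines)
        ) from exc
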