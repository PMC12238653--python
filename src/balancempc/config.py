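"""Run configuration: schema, validation, YAML loading.

A run is fully described by four sections -- ``body`` (anthropometry),
``platform`` (chirp), ``mpc`` (controller) and ``analysis`` (windowing and
transition detection).  Unknown keys are rejected so typos fail loudly.
All angles are radians, lengths metres, torques newton-metres.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .anthropometry import AnthropometricModel, build_anthropometry
from .mpc import MPCConfig
from .platform import PlatformSpec

__all__ = [
    "BodySection",
    "PlatformSection",
    "MPCSection",
    "AnalysisSection",
    "RunConfig",
    "load_config",
]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BodySection(_Section):
    total_mass: float = Field(68.4, gt=0, description="subject mass (kg)")
    total_height: float = Field(1.68, gt=0, description="stature (m)")
    table: str = "winter"
    gravity: float = Field(9.81, gt=0)

    def build(self) -> AnthropometricModel:
        return build_anthropometry(self.total_mass, self.total_height, self.table, self.gravity)


class PlatformSection(_Section):
    amplitude: float = Field(0.002, ge=0, description="chirp amplitude (m)")
    f_start: float = Field(0.4, gt=0)
    f_end: float = 6.0
    duration: float = Field(280.0, gt=0, description="sweep duration (s)")
    phase0: float = 0.0

    def build(self) -> PlatformSpec:
        return PlatformSpec(self.amplitude, self.f_start, self.f_end, self.duration, self.phase0)


class MPCSection(_Section):
    np_horizon: int = Field(4, ge=1)
    nc_horizon: int = Field(2, ge=1)
    q_diag: list[float] = Field(default_factory=lambda: [10.0] * 6)
    r_diag: list[float] = Field(default_factory=lambda: [10.0, 10.0, 80.0])
    dt: float = Field(0.01, gt=0)
    tau_scale: float = Field(150.0, gt=0)
    phi_bound: float = Field(0.6, gt=0)
    phidot_bound: float = Field(6.0, gt=0)
    tau_bounds: list[float] = Field(default_factory=lambda: [150.0, 150.0, 200.0])
    dtau_bound: float = Field(50.0, gt=0)
    solver: str = "sqp"
    preview: bool = True

    def build(self) -> MPCConfig:
        data = self.model_dump(exclude={"preview"})
        return MPCConfig(**data)


class AnalysisSection(_Section):
    window_samples: int = Field(100, ge=2)
    persistence: int = Field(3, ge=1)
    pairs: list[str] = Field(default_factory=lambda: ["ankle-knee", "knee-hip", "cop-com"])
    sigmoid_min_range: float = Field(0.5, gt=0, le=1)


class RunConfig(_Section):
    """Validated top-level configuration; see section models for defaults."""

    body: BodySection = Field(default_factory=BodySection)
    platform: PlatformSection = Field(default_factory=PlatformSection)
    mpc: MPCSection = Field(default_factory=MPCSection)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; None gives all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    return RunConfig.model_validate(raw)
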