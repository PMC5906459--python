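"""Structured-text (JSON) run configuration.

A single config block carries the plate format, tube and flow settings,
transition timing, and carryover model. Unknown keys are rejected so typos
fail loudly; every field has a documented default matching the reference
hardware (22 cm × 250 µm inlet tube, 2 µL/s, ~2 s transitions)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .fluidics import CarryoverModel, FlowSpec, TubeSpec
from .plates import PlateSpec
from .scheduler import TimingProfile


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TubeConfig(_Strict):
    length_cm: float = 22.0
    inner_diameter_um: float = 250.0

    def to_spec(self) -> TubeSpec:
        return TubeSpec(self.length_cm, self.inner_diameter_um)


class FlowConfig(_Strict):
    flowrate_ul_s: float = 2.0
    solute_diffusivity_m2_s: float = 4.25e-10

    def to_spec(self) -> FlowSpec:
        return FlowSpec(self.flowrate_ul_s, self.solute_diffusivity_m2_s)


class TimingConfig(_Strict):
    t_close_out: float = 0.2
    t_open_bp: float = 0.1
    t_raise: float = 0.5
    t_move_per_well: float = 0.4
    t_lower: float = 0.5
    t_close_bp: float = 0.1
    t_open_out: float = 0.2

    def to_profile(self) -> TimingProfile:
        return TimingProfile(**self.model_dump())


class CarryoverConfig(_Strict):
    residual_fraction: float = 0.0032
    residual_sd: float = 4.7e-4
    wash_reduction: float = 0.1

    def to_model(self) -> CarryoverModel:
        return CarryoverModel(**self.model_dump())


class RunConfig(_Strict):
    plate_format: str = "96-medium"
    tube: TubeConfig = Field(default_factory=TubeConfig)
    flow: FlowConfig = Field(default_factory=FlowConfig)
    timing: TimingConfig = Field(default_factory=TimingConfig)
    carryover: CarryoverConfig = Field(default_factory=CarryoverConfig)
    seed: int = 0

    def plate(self) -> PlateSpec:
        return PlateSpec.from_format(self.plate_format)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1))

    def digest(self) -> str:
        """Stable hash of the configuration, logged with every run."""
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
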