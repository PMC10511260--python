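"""YAML run configuration: schema validation and defaults.

One document with sections ``geometry``, ``fluid``, ``transport``,
``dosimetry``, ``solver`` and ``outputs``; every key optional, unknown
keys rejected with the schema path of the failure.  Dosimetry values are
given in laboratory units (nmol/min/10⁶ cells, cells/cm², hours) and
converted at this boundary; geometry/fluid/transport are SI.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .dosimetry import DosimetryParams, FluidProperties, TransportProperties
from .geometry import ChamberGeometry

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Configuration file failed schema validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySection(_Strict):
    height: float = 5e-4
    membrane_area: float = 1.1312e-4
    port_width: float = 8e-4
    lead_length: float = 2e-3

    def build(self) -> ChamberGeometry:
        return ChamberGeometry(**self.model_dump())


class FluidSection(_Strict):
    dynamic_viscosity: float = 1.023e-3
    density: float = 1000.0

    def build(self) -> FluidProperties:
        return FluidProperties(**self.model_dump())


class TransportSection(_Strict):
    diffusion_coefficient: float = 2.00e-9
    inlet_concentration: float = 0.195

    def build(self) -> TransportProperties:
        return TransportProperties(**self.model_dump())


class DosimetrySection(_Strict):
    consumption_nmol_min_per_1e6_cells: float = 2.1
    seeding_density_per_cm2: float = 5e4
    division_time_h: float = 80.0
    culture_duration_h: float = 336.0

    def build(self) -> DosimetryParams:
        return DosimetryParams.from_lab_units(
            self.consumption_nmol_min_per_1e6_cells,
            self.seeding_density_per_cm2,
            self.division_time_h,
            self.culture_duration_h,
        )


class SolverSection(_Strict):
    resolution: int = Field(default=200, ge=16)
    rtol: float = Field(default=1e-10, gt=0)
    scheme: str = "auto"
    slice_nx: int = Field(default=240, ge=8)
    slice_nz: int = Field(default=40, ge=4)


class OutputsSection(_Strict):
    directory: str = "results"
    vtk: bool = False


class RunConfig(_Strict):
    """Validated run configuration with built domain objects on demand."""

    geometry: GeometrySection = Field(default_factory=GeometrySection)
    fluid: FluidSection = Field(default_factory=FluidSection)
    transport: TransportSection = Field(default_factory=TransportSection)
    dosimetry: DosimetrySection = Field(default_factory=DosimetrySection)
    solver: SolverSection = Field(default_factory=SolverSection)
    outputs: OutputsSection = Field(default_factory=OutputsSection)
    seed: int = 0


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML configuration; None gives all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            "/".join(str(p) for p in err["loc"]) + f": {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration {path}: {locs}") from exc
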