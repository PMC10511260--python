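"""Physical constants and oxygen-consumption dosimetry.

The chamber is perfused with culture medium whose properties are those of
water at 37 °C; dissolved oxygen enters at the inlet saturation
concentration and is consumed by the epithelial monolayer growing on the
membrane.  The consumption is modelled worst-case: the layer is taken at
its maximum density from day 0, i.e. the seeding density amplified by the
number of population doublings the culture undergoes over the experiment,
and the resulting areal uptake is imposed as a constant wall flux

    J = q_cell · σ · d        [mol O₂ / (m² s)]

with q_cell the basal per-cell uptake, σ the seeding density and
d = duration / division time the doubling count.  With the default
parameters (2.1 nmol/min/10⁶ cells, 5×10⁴ cells/cm², 14 days of culture,
80 h division time, d = 4.2) this gives J ≈ 7.3×10⁻⁸ mol/(m² s).

The growth factor enters linearly as d (not 2^d): the flux model scales
the initial density by the accumulated doubling count as a conservative
bound, and only the linear factor is consistent with the derived default
above.  See docs/methods.md for the discussion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import units

__all__ = [
    "FluidProperties",
    "TransportProperties",
    "DosimetryParams",
    "DosimetryResult",
    "compute_doublings",
    "oxygen_wall_flux",
]


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


@dataclass(frozen=True)
class FluidProperties:
    """Culture medium at 37 °C."""

    dynamic_viscosity: float = 1.023e-3  # Pa·s
    density: float = 1000.0  # kg/m³

    def __post_init__(self) -> None:
        if self.dynamic_viscosity <= 0 or self.density <= 0:
            raise InvalidParameterError("viscosity and density must be strictly positive")


@dataclass(frozen=True)
class TransportProperties:
    """Dissolved-oxygen transport in the medium."""

    diffusion_coefficient: float = 2.00e-9  # m²/s
    inlet_concentration: float = 0.195  # mol/m³

    def __post_init__(self) -> None:
        if self.diffusion_coefficient <= 0:
            raise InvalidParameterError("diffusion coefficient must be strictly positive")
        if self.inlet_concentration < 0:
            raise InvalidParameterError("inlet concentration must be non-negative")


@dataclass(frozen=True)
class DosimetryParams:
    """Cell-culture inputs for the membrane oxygen-flux estimate.

    ``consumption_rate`` is stored in SI (mol O₂ per second per cell); use
    :meth:`from_lab_units` to construct from the units the assay literature
    quotes (nmol/min per 10⁶ cells).
    """

    consumption_rate: float = field(default=units.consumption_to_si(2.1))  # mol/s/cell
    seeding_density: float = field(default=units.density_per_cm2_to_per_m2(5e4))  # cells/m²
    division_time: float = 80.0  # h
    culture_duration: float = 336.0  # h (14 days)

    def __post_init__(self) -> None:
        if self.consumption_rate <= 0:
            raise InvalidParameterError("consumption rate must be strictly positive")
        if self.seeding_density < 0:
            raise InvalidParameterError("seeding density must be non-negative")
        if self.division_time <= 0 or self.culture_duration <= 0:
            raise InvalidParameterError("division time and culture duration must be positive")

    @classmethod
    def from_lab_units(
        cls,
        consumption_nmol_min_per_1e6_cells: float = 2.1,
        seeding_density_per_cm2: float = 5e4,
        division_time_h: float = 80.0,
        culture_duration_h: float = 336.0,
    ) -> "DosimetryParams":
        return cls(
            consumption_rate=units.consumption_to_si(consumption_nmol_min_per_1e6_cells),
            seeding_density=units.density_per_cm2_to_per_m2(seeding_density_per_cm2),
            division_time=division_time_h,
            culture_duration=culture_duration_h,
        )


@dataclass(frozen=True)
class DosimetryResult:
    """Doubling count and the derived constant membrane flux."""

    doublings: float  # dimensionless
    wall_flux: float  # mol O₂ / (m² s)


def compute_doublings(duration: float | str, division_time: float | str) -> float:
    """Number of population doublings over the culture period.

    Both arguments are durations, either in hours or as ``"<number> <unit>"``
    strings (s/min/h/d).  Returns duration / division_time.

    >>> compute_doublings("14 d", "80 h")
    4.2
    """
    dur_h = units.hours(duration)
    div_h = units.hours(division_time)
    if dur_h <= 0 or div_h <= 0:
        raise InvalidParameterError("durations must be strictly positive")
    return dur_h / div_h


def oxygen_wall_flux(params: DosimetryParams) -> DosimetryResult:
    """Constant oxygen wall flux consumed by the monolayer.

    Worst-case areal uptake: per-cell consumption × seeding density ×
    doubling count, in mol/(m² s).  Zero seeding density gives zero flux.
    """
    d = compute_doublings(params.culture_duration, params.division_time)
    flux = params.consumption_rate * params.seeding_density * d
    return DosimetryResult(doublings=d, wall_flux=flux)
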