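"""Depth-averaged creeping flow and membrane wall shear.

For a thin chamber (height h ≪ planform extent) at vanishing Reynolds
number, steady incompressible Stokes flow reduces to the Hele-Shaw
(lubrication) form: the depth-averaged velocity is

    ū = −h²/(12 μ) ∇p,          ∇·(h³/(12 μ) ∇p) = 0,

with the no-slip condition on top and bottom walls absorbed into the
parabolic (plane-Poiseuille) depth profile.  The wall shear stress
exerted on the cell layer at the membrane is then the parabolic-profile
wall gradient,

    τ = μ |∂u/∂z|_{z=0} = 6 μ |ū| / h,

reported as a magnitude.  Boundary conditions: uniform prescribed influx
across the inlet port, uniform outflux across the outlet port, no flux
through side walls, outlet reference pressure 0 Pa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fvm
from .dosimetry import FluidProperties
from .geometry import StructuredGrid
from .units import m3_s_to_ul_min, pa_to_mpa

__all__ = ["FlowSolution", "solve_flow", "analytic_plate_shear", "sweep_flow_rates"]


class ConfigurationError(ValueError):
    """The grid does not define a solvable perfusion problem."""


@dataclass(frozen=True)
class FlowSolution:
    """Pressure, depth-averaged velocity and membrane wall shear on the grid."""

    grid: StructuredGrid
    pressure: np.ndarray  # (nx, ny) Pa, NaN outside interior
    velocity_x: np.ndarray  # (nx, ny) m/s
    velocity_y: np.ndarray  # (nx, ny) m/s
    wall_shear: np.ndarray = field(repr=False)  # (nx, ny) Pa, NaN outside interior
    face_flux_x: np.ndarray = field(repr=False)  # (nx+1, ny) m³/s, +x positive
    face_flux_y: np.ndarray = field(repr=False)  # (nx, ny+1) m³/s
    flow_rate: float = 0.0  # m³/s
    fluid: FluidProperties = field(default_factory=FluidProperties)
    residuals: dict = field(default_factory=dict)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.velocity_x, self.velocity_y)

    def scaled(self, flow_rate: float) -> "FlowSolution":
        """Exact Stokes rescaling of all fields to another flow rate."""
        if self.flow_rate == 0:
            raise ValueError("cannot rescale a zero-flow solution")
        s = flow_rate / self.flow_rate
        return FlowSolution(
            grid=self.grid,
            pressure=self.pressure * s,
            velocity_x=self.velocity_x * s,
            velocity_y=self.velocity_y * s,
            wall_shear=self.wall_shear * abs(s),
            face_flux_x=self.face_flux_x * s,
            face_flux_y=self.face_flux_y * s,
            flow_rate=flow_rate,
            fluid=self.fluid,
            residuals=dict(self.residuals, rescaled_from=self.flow_rate),
        )


def analytic_plate_shear(flow_rate: float, width: float, height: float, viscosity: float) -> float:
    """Wall shear of plane-Poiseuille flow in a straight strip: 6 μ Q / (w h²).

    The closed-form limit of the chamber model far from ports; serves as the
    analytic oracle for strip geometries.  SI in, Pa out.
    """
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be strictly positive")
    if viscosity <= 0:
        raise ValueError("viscosity must be strictly positive")
    if flow_rate < 0:
        raise ValueError("flow rate must be non-negative")
    return 6.0 * viscosity * flow_rate / (width * height**2)


def _zero_solution(grid: StructuredGrid, fluid: FluidProperties) -> FlowSolution:
    shape = (grid.nx, grid.ny)
    z = np.where(grid.interior_mask, 0.0, np.nan)
    return FlowSolution(
        grid=grid,
        pressure=z.copy(),
        velocity_x=np.where(grid.interior_mask, 0.0, 0.0),
        velocity_y=np.zeros(shape),
        wall_shear=z.copy(),
        face_flux_x=np.zeros((grid.nx + 1, grid.ny)),
        face_flux_y=np.zeros((grid.nx, grid.ny + 1)),
        flow_rate=0.0,
        fluid=fluid,
        residuals={"relative_residual": 0.0, "method": "trivial", "unknowns": int(grid.interior_mask.sum())},
    )


def solve_flow(
    grid: StructuredGrid,
    fluid: FluidProperties,
    flow_rate: float,
    *,
    rtol: float = 1e-10,
) -> FlowSolution:
    """Solve the depth-averaged pressure equation and derive shear.

    ``flow_rate`` is volumetric, m³/s.  Raises :class:`ConfigurationError`
    when the grid has no inlet or no outlet cells.
    """
    if flow_rate < 0:
        raise ValueError("flow rate must be non-negative")
    interior = grid.interior_mask
    n_in = int(grid.inlet_mask.sum())
    n_out = int(grid.outlet_mask.sum())
    if int(interior.sum()) == 0:
        raise ConfigurationError("empty planform: nothing to solve")
    if n_in == 0 or n_out == 0:
        raise ConfigurationError("grid must expose inlet and outlet port cells")
    if flow_rate == 0:
        return _zero_solution(grid, fluid)

    h = grid.geometry.height
    mu = fluid.dynamic_viscosity
    reynolds = fluid.density * flow_rate / (grid.geometry.port_width * mu)
    if reynolds >= 1.0:
        warnings.warn(
            f"port Reynolds number {reynolds:.2f} >= 1: creeping-flow model "
            "validity is marginal",
            stacklevel=2,
        )

    k = h**3 / (12.0 * mu)  # face transmissibility, m³/(s·Pa)
    rhs = np.zeros((grid.nx, grid.ny))
    rhs[grid.inlet_mask] = flow_rate / n_in
    rhs[grid.outlet_mask] -= flow_rate / n_out

    problem = fvm.assemble(interior, k, rhs=rhs, constrain_mean=True)
    pressure, diag = fvm.solve_cells(problem, rtol=rtol)

    # gauge: outlet reference pressure 0 Pa
    pressure = pressure - np.nanmean(pressure[grid.outlet_mask])

    # face fluxes: interior faces from the two-point gradient, port boundary
    # faces carry the prescribed uniform flux, wall faces carry none
    qx = np.zeros((grid.nx + 1, grid.ny))
    qy = np.zeros((grid.nx, grid.ny + 1))
    pa, pb = pressure[:-1, :], pressure[1:, :]
    both_x = interior[:-1, :] & interior[1:, :]
    qx[1:-1, :][both_x] = k * (pa[both_x] - pb[both_x])
    pa, pb = pressure[:, :-1], pressure[:, 1:]
    both_y = interior[:, :-1] & interior[:, 1:]
    qy[:, 1:-1][both_y] = k * (pa[both_y] - pb[both_y])
    # prescribed port fluxes on the domain boundary (west inlet, east outlet)
    qx[0, grid.inlet_mask[0, :]] = flow_rate / n_in
    qx[-1, grid.outlet_mask[-1, :]] = flow_rate / n_out

    area_flux = h * grid.cell_size  # m², converts face flux to velocity
    ux = 0.5 * (qx[:-1, :] + qx[1:, :]) / area_flux
    uy = 0.5 * (qy[:, :-1] + qy[:, 1:]) / area_flux
    ux = np.where(interior, ux, 0.0)
    uy = np.where(interior, uy, 0.0)

    shear = np.where(interior, 6.0 * mu * np.hypot(ux, uy) / h, np.nan)

    # conservation diagnostic: the face-flux divergence (port boundary faces
    # included) must vanish in every interior cell
    div = qx[1:, :] - qx[:-1, :] + qy[:, 1:] - qy[:, :-1]
    diag = dict(diag)
    diag["max_divergence_rel"] = float(np.abs(div[interior]).max() / flow_rate)
    diag["reynolds_port"] = reynolds

    return FlowSolution(
        grid=grid,
        pressure=pressure,
        velocity_x=ux,
        velocity_y=uy,
        wall_shear=shear,
        face_flux_x=qx,
        face_flux_y=qy,
        flow_rate=flow_rate,
        fluid=fluid,
        residuals=diag,
    )


def sweep_flow_rates(
    grid: StructuredGrid,
    fluid: FluidProperties,
    rates: "list[float] | np.ndarray",
    *,
    shear_threshold: float = 2e-3,
    rtol: float = 1e-10,
) -> pd.DataFrame:
    """Membrane shear dosimetry over a set of flow rates (m³/s).

    Stokes flow is linear in the flow rate, so the field is solved once and
    rescaled exactly; each row reports the membrane-averaged shear, the
    maximum shear and the membrane-area fraction above ``shear_threshold``
    (Pa).  Columns use the laboratory units of the device literature.
    """
    rates = list(np.atleast_1d(np.asarray(rates, dtype=float)))
    if len(rates) == 0:
        raise ValueError("empty flow-rate list")
    if any(r <= 0 for r in rates):
        raise ValueError("flow rates must be strictly positive")
    from .metrics import area_average, area_fraction_above

    base = solve_flow(grid, fluid, rates[0], rtol=rtol)
    rows = []
    for rate in rates:
        sol = base if rate == rates[0] else base.scaled(rate)
        mask = grid.membrane_mask
        rows.append(
            {
                "rate_ul_min": m3_s_to_ul_min(rate),
                "mean_shear_mPa": pa_to_mpa(area_average(sol.wall_shear, mask)),
                "max_shear_mPa": pa_to_mpa(float(np.nanmax(sol.wall_shear[mask]))),
                "frac_above_2mPa": area_fraction_above(sol.wall_shear, mask, shear_threshold),
            }
        )
    return pd.DataFrame(rows)
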