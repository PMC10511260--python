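"""Steady oxygen transport with a constant consumption flux at the cells.

Two complementary reduced models of the advection–diffusion equation
∇·(−D∇c) + u·∇c = 0 with the membrane uptake J as the only sink
(worst case: the cells are oxygenated from the apical chamber alone):

* ``solve_oxygen_planform`` — depth-averaged 2-D (x, y) model on the same
  grid as the flow solution; the membrane flux enters as a volumetric
  sink J/h in membrane cells.  Captures the planform distribution and
  lateral stagnation zones, averages the vertical boundary layer away.

* ``solve_oxygen_slice`` — vertical 2-D (x, z) model of an equal-area
  rectangular channel with the plane-Poiseuille profile
  u(z) = 6 ū (z/h)(1 − z/h) and the constant flux on the bottom wall
  (the developing Graetz-type concentration boundary layer the planform
  model cannot see).

Boundary conditions in both: inlet Dirichlet at the saturation
concentration, advective outflow at the outlet, zero flux through every
other wall.  Advection is upwinded whenever the grid Péclet number
exceeds 2 (scheme="auto"); the switch is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import fvm
from .dosimetry import DosimetryResult, FluidProperties, TransportProperties
from .flow import FlowSolution
from .geometry import ChamberGeometry, StructuredGrid

__all__ = ["OxygenField", "solve_oxygen_planform", "solve_oxygen_slice", "mixed_cup_outlet"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OxygenField:
    """Dissolved-oxygen field with its mass-balance bookkeeping."""

    concentration: np.ndarray = field(repr=False)  # mol/m³; planform (nx,ny), slice (nx,nz)
    model_kind: str  # "planform" | "slice"
    inlet_concentration: float  # mol/m³
    wall_flux: float  # mol/(m² s)
    min_membrane: float  # mol/m³, minimum over the membrane cells
    outlet_mixed_cup: float  # mol/m³, flow-weighted outlet average
    balance_report: dict  # inflow / outflow / consumed, mol/s
    oxygen_deficient: bool  # True when the sink drives the field negative
    coords: dict = field(default_factory=dict, repr=False)

    @property
    def balance_residual(self) -> float:
        return self.balance_report["relative_residual"]


def mixed_cup_outlet(
    inlet_concentration: float, flow_rate: float, flux: float, membrane_area: float
) -> float:
    """Analytic outlet mixed-cup concentration: C_in − J·A/Q.

    The global steady mass balance of any model with the same sink; used
    as the cross-check oracle for both PDE solvers and as the 0-D device
    model in serial chains.
    """
    if flow_rate <= 0:
        raise ValueError("mixed-cup concentration undefined for non-positive flow rate")
    return inlet_concentration - flux * membrane_area / flow_rate


def _resolve_scheme(scheme: str, peclet: float) -> str:
    if scheme == "auto":
        return "upwind" if peclet > 2.0 else "central"
    if scheme == "central" and peclet > 2.0:
        log.warning(
            "grid Péclet %.2f > 2: switching central → upwind to keep the discrete field bounded",
            peclet,
        )
        return "upwind"
    return scheme


def solve_oxygen_planform(
    grid: StructuredGrid,
    flow: FlowSolution,
    transport: TransportProperties,
    flux: DosimetryResult,
    *,
    scheme: str = "auto",
    rtol: float = 1e-10,
) -> OxygenField:
    """Depth-averaged oxygen transport on the flow grid."""
    if flow.grid is not grid and flow.grid.interior_mask.shape != grid.interior_mask.shape:
        raise ValueError("flow solution was computed on a different grid")
    interior = grid.interior_mask
    h = grid.geometry.height
    D = transport.diffusion_coefficient
    c_in = transport.inlet_concentration
    J = flux.wall_flux

    g = D * h  # diffusive face conductance (m³/s equivalent)
    qmax = max(float(np.abs(flow.face_flux_x).max()), float(np.abs(flow.face_flux_y).max()))
    peclet = qmax / g if g > 0 else np.inf
    used = _resolve_scheme(scheme, peclet)

    n_in = int(grid.inlet_mask.sum())
    n_out = int(grid.outlet_mask.sum())
    q_in = flow.flow_rate / n_in if n_in else 0.0
    q_out = flow.flow_rate / n_out if n_out else 0.0

    rhs = np.zeros((grid.nx, grid.ny))
    rhs[grid.inlet_mask] += q_in * c_in  # advected inflow at saturation
    rhs[grid.membrane_mask] -= J * grid.cell_area  # consumption sink
    diag_extra = np.zeros((grid.nx, grid.ny))
    diag_extra[grid.outlet_mask] += q_out  # advective outflow of the local c

    # inlet Dirichlet through a ghost half-cell diffusive coupling
    dirichlet = [(i, j, 2.0 * g, c_in) for i, j in zip(*np.nonzero(grid.inlet_mask))]

    problem = fvm.assemble(
        interior,
        g,
        qx=flow.face_flux_x,
        qy=flow.face_flux_y,
        scheme=used,
        rhs=rhs,
        diag_extra=diag_extra,
        dirichlet=dirichlet,
    )
    conc, diag = fvm.solve_cells(problem, rtol=rtol)

    out_c = conc[grid.outlet_mask]
    mixed = float(np.sum(q_out * out_c) / flow.flow_rate) if flow.flow_rate > 0 else float(np.nanmean(conc[interior]))
    in_c = conc[grid.inlet_mask]
    inflow = flow.flow_rate * c_in + float(np.sum(2.0 * g * (c_in - in_c)))
    outflow = float(np.sum(q_out * out_c))
    consumed = J * grid.mask_area(grid.membrane_mask)
    scale = max(abs(inflow), abs(consumed), 1e-300)
    balance = {
        "inflow_mol_s": inflow,
        "outflow_mol_s": outflow,
        "consumed_mol_s": consumed,
        "relative_residual": abs(inflow - outflow - consumed) / scale,
        "solver": diag,
        "scheme": used,
        "grid_peclet": peclet,
    }
    cmin = float(np.nanmin(conc[grid.membrane_mask])) if grid.membrane_mask.any() else float(np.nanmin(conc[interior]))
    return OxygenField(
        concentration=conc,
        model_kind="planform",
        inlet_concentration=c_in,
        wall_flux=J,
        min_membrane=cmin,
        outlet_mixed_cup=mixed,
        balance_report=balance,
        oxygen_deficient=bool(cmin < 0.0),
        coords={"x": grid.x, "y": grid.y},
    )


def solve_oxygen_slice(
    geometry: ChamberGeometry,
    fluid: FluidProperties,
    transport: TransportProperties,
    flux: DosimetryResult,
    flow_rate: float,
    *,
    effective_width: float | None = None,
    length: float | None = None,
    nx: int = 240,
    nz: int = 40,
    scheme: str = "auto",
    rtol: float = 1e-10,
    source: np.ndarray | None = None,
    membrane_span: tuple[float, float] | None = None,
) -> OxygenField:
    """Vertical-slice (x, z) oxygen transport with a bottom wall flux.

    The chamber is mapped to an equal-area rectangle: default length = the
    membrane diameter, effective width = membrane_area / length, so the
    bottom wall carries the full membrane uptake J·A.  ``source`` is an
    optional (nx, nz) volumetric source array (mol/s per cell) used by
    manufactured-solution verification.
    """
    if flow_rate < 0:
        raise ValueError("flow rate must be non-negative")
    h = geometry.height
    R = geometry.membrane_radius
    L = length if length is not None else 2.0 * R
    w = effective_width if effective_width is not None else geometry.membrane_area / L
    if w <= 0 or L <= 0:
        raise ValueError("effective width and length must be strictly positive")
    D = transport.diffusion_coefficient
    c_in = transport.inlet_concentration
    J = flux.wall_flux
    dx, dz = L / nx, h / nz
    z = dz * (np.arange(nz) + 0.5)
    x = dx * (np.arange(nx) + 0.5)
    u_mean = flow_rate / (w * h)
    u = 6.0 * u_mean * (z / h) * (1.0 - z / h)  # plane Poiseuille

    peclet = float(np.max(u)) * dx / D if D > 0 else np.inf
    used = _resolve_scheme(scheme, peclet)

    # advective x-face fluxes (m³/s through a face of height dz, width w)
    qx = np.zeros((nx + 1, nz))
    qx[1:-1, :] = u[None, :] * dz * w
    gx = D * dz * w / dx
    gz = D * dx * w / dz
    n = nx * nz

    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    idx = np.arange(n).reshape(nx, nz)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(np.asarray(r).ravel())
        cols.append(np.asarray(c).ravel())
        vals.append(np.broadcast_to(v, np.asarray(r).shape).ravel().astype(float))

    # x faces between i and i+1
    a, b = idx[:-1, :], idx[1:, :]
    add(a, a, gx); add(b, b, gx); add(a, b, -gx); add(b, a, -gx)
    qf = qx[1:-1, :]
    if used == "upwind":
        qp, qm = np.maximum(qf, 0.0), np.minimum(qf, 0.0)
        add(a, a, qp); add(b, a, -qp); add(a, b, qm); add(b, b, -qm)
    else:
        add(a, a, 0.5 * qf); add(a, b, 0.5 * qf); add(b, a, -0.5 * qf); add(b, b, -0.5 * qf)
    # z faces between k and k+1 (diffusion only: vertical advection is zero)
    a, b = idx[:, :-1], idx[:, 1:]
    add(a, a, gz); add(b, b, gz); add(a, b, -gz); add(b, a, -gz)

    rhs = np.zeros((nx, nz))
    # inlet: advected inflow at c_in plus Dirichlet ghost coupling
    q_in_face = u * dz * w
    rhs[0, :] += q_in_face * c_in
    add(idx[0, :], idx[0, :], 2.0 * gx)
    rhs[0, :] += 2.0 * gx * c_in
    # outlet: advective outflow of the local concentration
    add(idx[-1, :], idx[-1, :], q_in_face)
    # bottom wall: constant consumption flux over the membrane span
    if membrane_span is None:
        span = np.ones(nx, dtype=bool)
    else:
        span = (x >= membrane_span[0]) & (x <= membrane_span[1])
    rhs[span, 0] -= J * dx * w
    if source is not None:
        rhs += source

    A = sp.coo_matrix((np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)).tocsr()
    c = spla.spsolve(A.tocsc(), rhs.ravel()).reshape(nx, nz)
    res = float(np.linalg.norm(A @ c.ravel() - rhs.ravel()) / max(np.linalg.norm(rhs.ravel()), 1e-300))

    q_total = float(np.sum(q_in_face))
    if q_total > 0:
        mixed = float(np.sum(q_in_face * c[-1, :]) / q_total)
    else:
        mixed = float(np.mean(c))
    inflow = q_total * c_in + float(np.sum(2.0 * gx * (c_in - c[0, :])))
    outflow = float(np.sum(q_in_face * c[-1, :]))
    consumed = J * dx * w * float(span.sum())
    src_total = float(np.sum(source)) if source is not None else 0.0
    scale = max(abs(inflow), abs(consumed), 1e-300)
    balance = {
        "inflow_mol_s": inflow,
        "outflow_mol_s": outflow,
        "consumed_mol_s": consumed,
        "relative_residual": abs(inflow + src_total - outflow - consumed) / scale,
        "solver": {"relative_residual": res, "method": "splu", "unknowns": n},
        "scheme": used,
        "grid_peclet": peclet,
    }
    cmin = float(np.min(c[span, 0]))
    return OxygenField(
        concentration=c,
        model_kind="slice",
        inlet_concentration=c_in,
        wall_flux=J,
        min_membrane=cmin,
        outlet_mixed_cup=mixed,
        balance_report=balance,
        oxygen_deficient=bool(cmin < 0.0),
        coords={"x": x, "z": z, "width": w, "length": L},
    )
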