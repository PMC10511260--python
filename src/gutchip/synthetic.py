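"""Synthetic data with known ground truth, and manufactured PDE solutions.

Everything the pipeline consumes can be generated here without any
download: plate-reader fluorescence for the FITC-dextran transport assay
(two-fold serial-dilution calibration ladder plus multiplicative Gaussian
noise, truncated at zero), triplicate chopstick-electrode resistance
readings, and exact manufactured solutions used to verify both
finite-volume solvers.

All generators are pure functions of (truth, seed): identical seeds give
identical datasets.  Noise is multiplicative Gaussian on signals,
truncated at zero (a lognormal-like approximation of plate-reader and
voltohmmeter noise).

Conventions matched to :mod:`gutchip.assays`: calibration ladder signals
are blank-subtracted (net) fluorescence, basal readings are raw (blank
included), so the reduction pipeline's blank subtraction round-trips
exactly in the noiseless limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import fvm
from .assays import CalibrationCurve, PermeabilityAssay, TeerMeasurement
from .dosimetry import FluidProperties, TransportProperties
from .geometry import StructuredGrid

__all__ = [
    "SyntheticAssayTruth",
    "ManufacturedCase",
    "gen_permeability_assay",
    "gen_teer_series",
    "manufactured_flow_case",
    "manufactured_oxygen_case",
    "run_manufactured_flow",
    "run_manufactured_oxygen",
    "run_manufactured_slice",
]

#: default plate-reader sensitivity, a.u. per μg/ml of FITC-dextran
_CAL_SLOPE = 120.0
#: fresh-medium background fluorescence, a.u.
_BLANK_FLUOR = 60.0
#: blank insert resistance (collagen-coated, no cells), Ω
_BLANK_OHM = 125.0


@dataclass(frozen=True)
class SyntheticAssayTruth:
    """Ground truth injected into generated assay datasets."""

    true_papp: float = 2.0e-6  # cm/s
    true_teer: float = 650.0  # Ω·cm²
    noise_sd: float = 0.02  # fractional, multiplicative
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.true_papp < 0 or self.true_teer < 0:
            raise ValueError("ground-truth values must be non-negative")


def _noisy(rng: np.random.Generator, values: np.ndarray, sd: float) -> np.ndarray:
    if sd == 0:
        return values
    return np.maximum(values * (1.0 + sd * rng.standard_normal(values.shape)), 0.0)


def gen_permeability_assay(truth: SyntheticAssayTruth) -> PermeabilityAssay:
    """Simulate one FITC-dextran transport assay consistent with ``true_papp``.

    Builds the 7-level two-fold ladder 50 → 0.78125 μg/ml and duplicate
    basal readings for an incubation of 12 600 s at C₀ = 1 mg/ml over
    1.131 cm², with the transported amount dQ = P_app·C₀·A·dt distributed
    in the 0.75 ml basal volume.
    """
    rng = np.random.default_rng(truth.seed)
    ladder = 50.0 / 2.0 ** np.arange(7)  # μg/ml, ends at 0.78125
    cal_signals = _noisy(rng, _CAL_SLOPE * ladder, truth.noise_sd)
    calibration = CalibrationCurve(concentrations=tuple(ladder), signals=tuple(cal_signals))

    dt, c0_mg_ml, area, volume = 12_600.0, 1.0, 1.131, 0.75
    dq_ug = truth.true_papp * (c0_mg_ml * 1000.0) * area * dt  # μg transported
    basal_conc = dq_ug / volume  # μg/ml
    raw = _BLANK_FLUOR + _CAL_SLOPE * basal_conc
    readings = _noisy(rng, np.full(2, raw), truth.noise_sd)
    return PermeabilityAssay(
        basal_fluorescence_readings=tuple(readings),
        blank_fluorescence=_BLANK_FLUOR,
        calibration=calibration,
        incubation_time=dt,
        initial_concentration=c0_mg_ml,
        membrane_area=area,
        basal_volume_ml=volume,
    )


def gen_teer_series(truth: SyntheticAssayTruth) -> TeerMeasurement:
    """Simulate triplicate resistance readings consistent with ``true_teer``."""
    rng = np.random.default_rng(truth.seed)
    area = 1.131
    r_true = _BLANK_OHM + truth.true_teer / area
    readings = _noisy(rng, np.full(3, r_true), truth.noise_sd)
    return TeerMeasurement(
        resistance_readings=tuple(readings),
        blank_resistance=_BLANK_OHM,
        membrane_area=area,
    )


@dataclass(frozen=True)
class ManufacturedCase:
    """An exact field whose implied boundary/source data verify a solver."""

    kind: str
    exact: Callable[[np.ndarray, np.ndarray], np.ndarray] = field(repr=False)
    grad: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]] = field(repr=False)
    source: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = field(default=None, repr=False)


def manufactured_flow_case(kind: str = "dipole") -> ManufacturedCase:
    """Exact harmonic pressure fields for the depth-averaged flow solver.

    * ``linear`` — p = x (uniform flow): exactly representable by the
      two-point scheme at any resolution.
    * ``dipole`` — p = Re log((ζ−a)/(ζ+a)) with poles a = ±1.5 R outside
      the disc: a smooth source/sink potential with curved streamlines.
    * ``constant`` — p = 1: zero boundary flux, zero velocity.
    """
    if kind == "linear":
        return ManufacturedCase(
            kind=kind,
            exact=lambda x, y: x,
            grad=lambda x, y: (np.ones_like(x), np.zeros_like(y)),
        )
    if kind == "constant":
        return ManufacturedCase(
            kind=kind,
            exact=lambda x, y: np.ones_like(x),
            grad=lambda x, y: (np.zeros_like(x), np.zeros_like(y)),
        )
    if kind == "dipole":
        # coordinates are in units of the disc radius: poles sit at ±1.5
        def exact(x, y):
            z = x + 1j * y
            a = 1.5
            return np.log(np.abs(z - a) / np.abs(z + a))

        def grad(x, y):
            z = x + 1j * y
            a = 1.5
            w = 1.0 / (z - a) - 1.0 / (z + a)  # d/dz of log((z−a)/(z+a))
            return np.real(w), -np.imag(w)

        return ManufacturedCase(kind=kind, exact=exact, grad=grad)
    raise ValueError(f"unknown manufactured flow kind {kind!r}")


def _boundary_flux_rhs(grid: StructuredGrid, grad, k: float) -> np.ndarray:
    """Per-cell rhs carrying exact inward fluxes −k∇p·n on boundary faces."""
    interior = grid.interior_mask
    dx = grid.cell_size
    rhs = np.zeros((grid.nx, grid.ny))
    pad = np.zeros((grid.nx + 2, grid.ny + 2), dtype=bool)
    pad[1:-1, 1:-1] = interior
    X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
    for di, dj, nxv, nyv in ((-1, 0, -1.0, 0.0), (1, 0, 1.0, 0.0), (0, -1, 0.0, -1.0), (0, 1, 0.0, 1.0)):
        nb = pad[1 + di : grid.nx + 1 + di, 1 + dj : grid.ny + 1 + dj]
        bmask = interior & ~nb  # boundary face on this side
        xf = X[bmask] + 0.5 * dx * nxv
        yf = Y[bmask] + 0.5 * dx * nyv
        gx, gy = grad(xf, yf)
        # inward volumetric flux −(−k∇p)·n_out through the face, midpoint rule
        rhs[bmask] += k * (gx * nxv + gy * nyv) * dx
    return rhs


def run_manufactured_flow(case: ManufacturedCase, grid: StructuredGrid, *, k: float = 1.0) -> dict:
    """Solve ∇·(k∇p) = (−source) with the case's exact Neumann data; return errors.

    The discrete pressure is gauge-fixed by matching means before the error
    norm.  Returns L2 and max errors plus the cell size.
    """
    interior = grid.interior_mask
    rhs = _boundary_flux_rhs(grid, case.grad, k)
    if case.source is not None:
        X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
        rhs += np.where(interior, case.source(X, Y) * grid.cell_area, 0.0)
    problem = fvm.assemble(interior, k, rhs=rhs, constrain_mean=True)
    p, diag = fvm.solve_cells(problem)
    X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
    exact = case.exact(X, Y)
    err = (p - np.mean(p[interior])) - (exact - np.mean(exact[interior]))
    l2 = float(np.sqrt(np.mean(err[interior] ** 2)))
    return {
        "l2_error": l2,
        "max_error": float(np.max(np.abs(err[interior]))),
        "cell_size": grid.cell_size,
        "diagnostics": diag,
    }


def manufactured_oxygen_case(kind: str = "diffusion") -> ManufacturedCase:
    """Exact concentration fields with matching sources for the transport solvers.

    * ``constant`` — uniform field, zero source (discretely exact).
    * ``diffusion`` — c = cos(πx)cos(πy) on the unit square with zero-flux
      boundaries and source s = 2π²D c: diffusion-dominated, exercises the
      central scheme at second order.
    * ``advection`` — same field with a uniform velocity and the matching
      advective source term: exercises the upwind scheme at first order.
    """
    if kind == "constant":
        return ManufacturedCase(
            kind=kind,
            exact=lambda x, y: np.ones_like(x),
            grad=lambda x, y: (np.zeros_like(x), np.zeros_like(y)),
            source=lambda x, y: np.zeros_like(x),
        )
    if kind in ("diffusion", "advection"):
        def exact(x, y):
            return np.cos(np.pi * x) * np.cos(np.pi * y)

        def grad(x, y):
            return (
                -np.pi * np.sin(np.pi * x) * np.cos(np.pi * y),
                -np.pi * np.cos(np.pi * x) * np.sin(np.pi * y),
            )

        return ManufacturedCase(kind=kind, exact=exact, grad=grad, source=None)
    raise ValueError(f"unknown manufactured oxygen kind {kind!r}")


def _unit_square_grid(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    dx = 1.0 / n
    x = dx * (np.arange(n) + 0.5)
    X, Y = np.meshgrid(x, x, indexing="ij")
    interior = np.ones((n, n), dtype=bool)
    return X, Y, interior, dx


def run_manufactured_oxygen(
    case: ManufacturedCase, n: int, *, diffusivity: float = 1.0, velocity: float = 0.0, scheme: str = "central"
) -> dict:
    """Verify the planform transport discretization on the unit square.

    Zero-flux boundaries (the manufactured field has ∂c/∂n = 0 on the unit
    square), optional uniform advection u in +x with its exact inflow /
    outflow boundary data, and the matching volumetric source.
    """
    X, Y, interior, dx = _unit_square_grid(n)
    g = diffusivity  # face conductance on the unit-thickness square, dx/dx = 1
    exact = case.exact(X, Y)

    qx = np.zeros((n + 1, n))
    rhs = np.zeros((n, n))
    diag_extra = np.zeros((n, n))
    if case.kind == "constant":
        pass  # zero source, zero boundary flux
    else:
        lap = -2.0 * np.pi**2 * exact
        adv = velocity * (-np.pi * np.sin(np.pi * X) * np.cos(np.pi * Y))
        rhs += (adv - diffusivity * lap) * dx * dx
        if velocity != 0.0:
            qx[1:-1, :] = velocity * dx  # uniform advective face flux
            # inflow at x=0 carries the exact boundary concentration cos(πy)
            rhs[0, :] += velocity * dx * np.cos(np.pi * Y[0, :])
            diag_extra[-1, :] += velocity * dx  # upwind outflow of the local value

    constrained = velocity == 0.0  # pure-Neumann diffusion: fix the gauge
    problem = fvm.assemble(
        interior,
        g,
        qx=qx if velocity != 0.0 else None,
        qy=None,
        scheme=scheme,
        rhs=rhs,
        diag_extra=diag_extra,
        constrain_mean=constrained,
    )
    c, diag = fvm.solve_cells(problem)
    err = c - exact
    if constrained:
        err = err - np.mean(err[interior])
    return {
        "l2_error": float(np.sqrt(np.mean(err[interior] ** 2))),
        "max_error": float(np.max(np.abs(err[interior]))),
        "cell_size": dx,
        "diagnostics": diag,
    }


def run_manufactured_slice(n: int, *, scheme: str = "central", flow_rate: float = 0.0) -> dict:
    """Verify the vertical-slice solver against an exact field.

    Manufactured field c = 1 + (1 − cos(πx/L))·cos(πz/h): constant (= the
    inlet Dirichlet value) at x = 0 with zero normal gradient there, zero
    flux through top and bottom walls, zero x-gradient at the outlet — all
    compatible with the slice solver's physical boundary conditions, so the
    only remaining error is discretization.  With flow, the plane-Poiseuille
    advective term joins the manufactured source through the solver's
    ``source`` hook.
    """
    from .geometry import ChamberGeometry
    from .oxygen import solve_oxygen_slice

    geom = ChamberGeometry()
    h = geom.height
    L = 2.0 * geom.membrane_radius
    w = geom.membrane_area / L
    D = 2.0e-9
    nx, nz = 6 * n, n
    dx, dz = L / nx, h / nz
    x = dx * (np.arange(nx) + 0.5)
    z = dz * (np.arange(nz) + 0.5)
    X, Z = np.meshgrid(x, z, indexing="ij")
    exact = 1.0 + (1.0 - np.cos(np.pi * X / L)) * np.cos(np.pi * Z / h)
    u_mean = flow_rate / (w * h)
    u = 6.0 * u_mean * (Z / h) * (1.0 - Z / h)
    d2x = (np.pi / L) ** 2 * np.cos(np.pi * X / L) * np.cos(np.pi * Z / h)
    d2z = -((np.pi / h) ** 2) * (1.0 - np.cos(np.pi * X / L)) * np.cos(np.pi * Z / h)
    dcdx = (np.pi / L) * np.sin(np.pi * X / L) * np.cos(np.pi * Z / h)
    source_density = u * dcdx - D * (d2x + d2z)  # mol/(m³ s)
    source = source_density * dx * dz * w

    transport = TransportProperties(diffusion_coefficient=D, inlet_concentration=1.0)
    from .dosimetry import DosimetryResult

    fieldr = solve_oxygen_slice(
        geom,
        FluidProperties(),
        transport,
        DosimetryResult(doublings=0.0, wall_flux=0.0),
        flow_rate,
        nx=nx,
        nz=nz,
        scheme=scheme,
        source=source,
    )
    c = fieldr.concentration
    err = c - exact
    # the inlet Dirichlet (c_in = 1 = exact value at x = 0) pins the level
    return {
        "l2_error": float(np.sqrt(np.mean(err**2))),
        "max_error": float(np.max(np.abs(err))),
        "cell_size": dx,
    }
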