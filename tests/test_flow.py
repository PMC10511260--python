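"""Depth-averaged flow solver: oracles, conservation, linearity, shear."""

import numpy as np
import pytest

from gutchip import (
    FluidProperties,
    analytic_plate_shear,
    area_average,
    make_grid,
    solve_flow,
    sweep_flow_rates,
)
from gutchip.flow import ConfigurationError
from gutchip.units import pa_to_mpa, ul_min_to_m3_s
from tests.conftest import Q5, Q30


def test_analytic_plate_shear_hand_value():
    """6μQ/(wh²) at 30 μl/min, 10 mm, 0.5 mm, 1.023 mPa·s → 1.228 mPa."""
    tau = analytic_plate_shear(Q30, 0.010, 5e-4, 1.023e-3)
    assert tau == pytest.approx(1.228e-3, rel=1e-3)
    assert analytic_plate_shear(0.0, 0.01, 5e-4, 1.023e-3) == 0.0
    assert analytic_plate_shear(2 * Q30, 0.010, 5e-4, 1.023e-3) == pytest.approx(2 * tau, rel=1e-12)


def test_analytic_plate_shear_rejects_degenerate():
    with pytest.raises(ValueError):
        analytic_plate_shear(Q30, 0.0, 5e-4, 1e-3)
    with pytest.raises(ValueError):
        analytic_plate_shear(Q30, 0.01, 0.0, 1e-3)


def test_zero_flow_gives_zero_fields(grid64, fluid):
    sol = solve_flow(grid64, fluid, 0.0)
    interior = grid64.interior_mask
    assert np.allclose(sol.pressure[interior], 0.0)
    assert np.allclose(sol.wall_shear[grid64.membrane_mask], 0.0)
    assert np.allclose(sol.velocity_x, 0.0)


def test_strip_matches_plane_poiseuille_oracle(strip_geometry, fluid):
    """Uniform strip flow reproduces 6μQ/(wh²) membrane shear within 1%."""
    grid = make_grid(strip_geometry, 200)
    sol = solve_flow(grid, fluid, Q30)
    mean = area_average(sol.wall_shear, grid.membrane_mask)
    exact = analytic_plate_shear(Q30, 0.010, strip_geometry.height, fluid.dynamic_viscosity)
    assert mean == pytest.approx(exact, rel=0.01)


def test_flow_linearity_exact(grid64, fluid):
    """Stokes: doubling Q doubles every field to solver tolerance."""
    a = solve_flow(grid64, fluid, Q30)
    b = solve_flow(grid64, fluid, 2 * Q30)
    interior = grid64.interior_mask
    assert np.allclose(2 * a.pressure[interior], b.pressure[interior], rtol=1e-8, atol=1e-12)
    assert np.allclose(2 * a.wall_shear[grid64.membrane_mask], b.wall_shear[grid64.membrane_mask], rtol=1e-8)


def test_conservation_every_cell(flow30):
    """Face-flux divergence vanishes in every interior cell (inflow = outflow)."""
    assert flow30.residuals["max_divergence_rel"] < 1e-6


def test_inflow_equals_outflow(flow30):
    qx = flow30.face_flux_x
    inflow = qx[0, :].sum()
    outflow = qx[-1, :].sum()
    assert inflow == pytest.approx(flow30.flow_rate, rel=1e-12)
    assert outflow == pytest.approx(flow30.flow_rate, rel=1e-12)


def test_shear_is_parabolic_profile_of_speed(flow30):
    grid = flow30.grid
    mem = grid.membrane_mask
    mu = flow30.fluid.dynamic_viscosity
    h = grid.geometry.height
    expected = 6.0 * mu * flow30.speed[mem] / h
    assert np.allclose(flow30.wall_shear[mem], expected, rtol=1e-12)


def test_wall_shear_non_negative(flow30):
    assert (flow30.wall_shear[flow30.grid.membrane_mask] >= 0).all()


def test_no_outlet_is_configuration_error(geometry, fluid):
    from gutchip import ChamberGeometry

    grid = make_grid(ChamberGeometry(planform="empty"), 32)
    with pytest.raises(ConfigurationError):
        solve_flow(grid, fluid, Q30)


def test_sweep_reproduces_single_solve(grid64, fluid):
    table = sweep_flow_rates(grid64, fluid, [Q30])
    sol = solve_flow(grid64, fluid, Q30)
    mean = pa_to_mpa(area_average(sol.wall_shear, grid64.membrane_mask))
    assert table.mean_shear_mPa[0] == pytest.approx(mean, rel=1e-10)


def test_sweep_ratio_and_monotonicity(grid64, fluid):
    """Stokes linearity: SS(200)/SS(5) = 40 within 0.5%; monotone in Q."""
    rates = [ul_min_to_m3_s(r) for r in (5, 15, 30, 50, 200)]
    table = sweep_flow_rates(grid64, fluid, rates)
    assert len(table) == 5
    assert table.mean_shear_mPa.is_monotonic_increasing
    ratio = table.mean_shear_mPa.iloc[-1] / table.mean_shear_mPa.iloc[0]
    assert ratio == pytest.approx(40.0, rel=0.005)


def test_sweep_rejects_empty(grid64, fluid):
    with pytest.raises(ValueError):
        sweep_flow_rates(grid64, fluid, [])


def test_high_rate_warns_about_reynolds(grid64, fluid):
    with pytest.warns(UserWarning, match="Reynolds"):
        solve_flow(grid64, fluid, ul_min_to_m3_s(200.0))
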