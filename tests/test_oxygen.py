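"""Oxygen transport: balance oracle, bounds, monotonicity, model agreement."""

import numpy as np
import pytest

from gutchip import (
    DosimetryParams,
    DosimetryResult,
    TransportProperties,
    make_grid,
    mixed_cup_outlet,
    oxygen_wall_flux,
    solve_flow,
    solve_oxygen_planform,
    solve_oxygen_slice,
)
from gutchip.units import ul_min_to_m3_s
from tests.conftest import Q30

ZERO_FLUX = DosimetryResult(doublings=0.0, wall_flux=0.0)


@pytest.mark.parametrize(
    "c_in, rate_ul_min, flux, expected",
    [
        (0.195, 30.0, 7.34e-8, 0.1784),  # hand balance C_in − J·A/Q
        (0.195, 30.0, 0.0, 0.195),
        (0.195, 5.0, 7.34e-8, 0.0954),
    ],
)
def test_mixed_cup_hand_oracle(c_in, rate_ul_min, flux, expected):
    out = mixed_cup_outlet(c_in, ul_min_to_m3_s(rate_ul_min), flux, 1.1312e-4)
    assert out == pytest.approx(expected, abs=2e-4)


def test_mixed_cup_undefined_at_zero_flow():
    with pytest.raises(ValueError):
        mixed_cup_outlet(0.195, 0.0, 7.34e-8, 1.1312e-4)


def test_planform_zero_flux_uniform(grid64, fluid, transport):
    sol = solve_flow(grid64, fluid, Q30)
    ox = solve_oxygen_planform(grid64, sol, transport, ZERO_FLUX)
    interior = grid64.interior_mask
    assert np.allclose(ox.concentration[interior], transport.inlet_concentration, rtol=1e-9)
    assert not ox.oxygen_deficient


def test_planform_balance_and_mixed_cup(flow30, transport, wall_flux):
    ox = solve_oxygen_planform(flow30.grid, flow30, transport, wall_flux)
    assert ox.balance_residual < 1e-4
    oracle = mixed_cup_outlet(
        transport.inlet_concentration, flow30.flow_rate, wall_flux.wall_flux, flow30.grid.geometry.membrane_area
    )
    assert ox.outlet_mixed_cup == pytest.approx(oracle, rel=0.02)
    # concentration bounded by the inlet value when the membrane is the only sink
    interior = flow30.grid.interior_mask
    assert np.nanmax(ox.concentration[interior]) <= transport.inlet_concentration * (1 + 1e-9)
    assert ox.min_membrane > 0


def test_slice_balance_and_mixed_cup(geometry, fluid, transport, wall_flux):
    ox = solve_oxygen_slice(geometry, fluid, transport, wall_flux, Q30)
    assert ox.balance_residual < 1e-4
    oracle = mixed_cup_outlet(transport.inlet_concentration, Q30, wall_flux.wall_flux, geometry.membrane_area)
    assert ox.outlet_mixed_cup == pytest.approx(oracle, rel=0.02)


def test_planform_and_slice_agree(flow30, geometry, fluid, transport, wall_flux):
    a = solve_oxygen_planform(flow30.grid, flow30, transport, wall_flux)
    b = solve_oxygen_slice(geometry, fluid, transport, wall_flux, Q30)
    assert a.outlet_mixed_cup == pytest.approx(b.outlet_mixed_cup, rel=0.02)


def test_slice_zero_flow_zero_flux_uniform(geometry, fluid, transport):
    ox = solve_oxygen_slice(geometry, fluid, transport, ZERO_FLUX, 0.0, nx=60, nz=12)
    assert np.allclose(ox.concentration, transport.inlet_concentration, rtol=1e-9)


def test_min_oxygen_monotone_in_flux_and_flow(grid64, fluid, transport):
    """Min membrane O₂ falls with consumption and rises with perfusion."""
    rates = [ul_min_to_m3_s(q) for q in (10.0, 30.0, 90.0)]
    fluxes = [
        DosimetryResult(doublings=4.2, wall_flux=j * 7.35e-8) for j in (0.5, 1.0, 2.0)
    ]
    mins = np.empty((3, 3))
    for a, rate in enumerate(rates):
        sol = solve_flow(grid64, fluid, rate)
        for b, fx in enumerate(fluxes):
            mins[a, b] = solve_oxygen_planform(grid64, sol, transport, fx).min_membrane
    # non-increasing in J (columns), non-decreasing in Q (rows)
    assert (np.diff(mins, axis=1) <= 1e-12).all()
    assert (np.diff(mins, axis=0) >= -1e-12).all()


def test_deficiency_flagged_not_raised(grid64, fluid, transport):
    """A starved chamber reports oxygen deficiency instead of crashing."""
    sol = solve_flow(grid64, fluid, ul_min_to_m3_s(1.0))
    huge = DosimetryResult(doublings=4.2, wall_flux=3e-6)
    ox = solve_oxygen_planform(grid64, sol, transport, huge)
    assert ox.oxygen_deficient
    assert ox.min_membrane < 0


def test_operating_point_min_oxygen(flow30, transport):
    """At 30 μl/min with the worst-case flux the membrane stays oxygenated."""
    ox = solve_oxygen_planform(flow30.grid, flow30, transport, oxygen_wall_flux(DosimetryParams()))
    assert ox.min_membrane > 0.0
    assert ox.min_membrane < transport.inlet_concentration
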