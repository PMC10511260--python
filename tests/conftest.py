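import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gutchip import (
    ChamberGeometry,
    DosimetryParams,
    FluidProperties,
    TransportProperties,
    make_grid,
    oxygen_wall_flux,
    solve_flow,
)
from gutchip.units import ul_min_to_m3_s

Q30 = ul_min_to_m3_s(30.0)
Q5 = ul_min_to_m3_s(5.0)


@pytest.fixture(scope="session")
def geometry():
    return ChamberGeometry()


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def transport():
    return TransportProperties()


@pytest.fixture(scope="session")
def wall_flux():
    return oxygen_wall_flux(DosimetryParams())


@pytest.fixture(scope="session")
def grid200(geometry):
    """Production-resolution grid (200 cells across the membrane)."""
    return make_grid(geometry, 200)


@pytest.fixture(scope="session")
def grid64(geometry):
    """Coarse grid for cheap property checks."""
    return make_grid(geometry, 64)


@pytest.fixture(scope="session")
def flow30(grid200, fluid):
    """Reference flow solution at the 30 μl/min operating point."""
    return solve_flow(grid200, fluid, Q30)


@pytest.fixture(scope="session")
def strip_geometry():
    """Straight 10 mm wide strip: the analytic plane-Poiseuille oracle domain."""
    w = 0.005
    return ChamberGeometry(
        planform=[(-0.009, -w), (0.009, -w), (0.009, w), (-0.009, w)],
        lead_length=0.0,
    )


def l2_orders(errors):
    """Observed convergence orders from errors at successively doubled resolution."""
    e = np.asarray(errors, dtype=float)
    return np.log2(e[:-1] / e[1:])
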