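"""Apical hemi-chamber planform and structured grid construction.

The chamber is the thin (0.5 mm high) fluid space above the porous
membrane of a Transwell-like insert.  The default planform is the minimal
shape consistent with the device description: the circular membrane disc
(area 1.1312 cm², radius ≈ 6 mm) plus two straight rectangular port leads
of the millifluidic channel width, attached at diametrically opposite
points of the disc rim along the perfusion axis x.

Coordinates: origin at the membrane centre, x along the inlet→outlet
axis, cell-centred square cells, 0-based ``[i, j]`` indexing with
``i`` along x and ``j`` along y.  A cell belongs to the membrane iff its
centre lies inside the disc.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["ChamberGeometry", "StructuredGrid", "build_chamber", "make_grid"]


class InvalidGeometryError(ValueError):
    """Planform dimensions are inconsistent."""


@dataclass(frozen=True)
class ChamberGeometry:
    """Resolved apical hemi-chamber geometry (SI units)."""

    height: float = 5e-4  # m
    membrane_area: float = 1.1312e-4  # m²
    port_width: float = 8e-4  # m, admissible 5e-4–1e-3
    lead_length: float = 2e-3  # m, straight channel between port and disc rim
    planform: str | Sequence[tuple[float, float]] = "disc"

    def __post_init__(self) -> None:
        if self.height <= 0 or self.membrane_area <= 0:
            raise InvalidGeometryError("height and membrane area must be positive")
        if self.port_width <= 0:
            raise InvalidGeometryError("port width must be positive")
        if self.lead_length < 0:
            raise InvalidGeometryError("lead length must be non-negative")
        if self.port_width >= 2.0 * self.membrane_radius:
            raise InvalidGeometryError(
                f"port width {self.port_width:g} m does not fit the chamber "
                f"(membrane diameter {2 * self.membrane_radius:g} m)"
            )
        if not (5e-4 <= self.port_width <= 1e-3):
            warnings.warn(
                f"port width {self.port_width:g} m outside the millifluidic "
                "channel range 0.5–1 mm",
                stacklevel=2,
            )
        # thin-film validity: the depth-averaged flow model assumes h ≪ planform extent
        if self.height / (2.0 * self.membrane_radius) >= 0.1:
            warnings.warn(
                "aspect ratio height/diameter >= 0.1: the depth-averaged flow "
                "model is outside its validity range",
                stacklevel=2,
            )

    @property
    def membrane_radius(self) -> float:
        """Radius of the membrane disc, from its area."""
        return math.sqrt(self.membrane_area / math.pi)


def build_chamber(config: Mapping[str, object] | None = None) -> ChamberGeometry:
    """Resolve a ``geometry:`` configuration section into a ChamberGeometry.

    Accepted keys (all optional, SI units): ``height``, ``membrane_area``,
    ``port_width``, ``lead_length``, ``planform``.  Unknown keys are
    rejected.
    """
    config = dict(config or {})
    allowed = {"height", "membrane_area", "port_width", "lead_length", "planform"}
    unknown = set(config) - allowed
    if unknown:
        raise InvalidGeometryError(f"unknown geometry keys: {sorted(unknown)}")
    return ChamberGeometry(**config)  # type: ignore[arg-type]


@dataclass(frozen=True)
class StructuredGrid:
    """Uniform cell-centred Cartesian grid covering the planform bounding box."""

    geometry: ChamberGeometry
    nx: int
    ny: int
    cell_size: float  # m, square cells
    x: np.ndarray  # (nx,) cell-centre x coordinates
    y: np.ndarray  # (ny,) cell-centre y coordinates
    interior_mask: np.ndarray = field(repr=False)  # (nx, ny) bool
    membrane_mask: np.ndarray = field(repr=False)
    inlet_mask: np.ndarray = field(repr=False)
    outlet_mask: np.ndarray = field(repr=False)

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def mask_area(self, mask: np.ndarray) -> float:
        return float(mask.sum()) * self.cell_area


def _inside_polygon(vertices: Sequence[tuple[float, float]], X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    import shapely

    poly = shapely.Polygon(vertices)
    return shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)


def make_grid(geometry: ChamberGeometry, resolution: int) -> StructuredGrid:
    """Build the structured grid with membrane / interior / port masks.

    ``resolution`` is the number of cells across the membrane diameter;
    the grid extends by the port leads on both sides along x.  The grid is
    a deterministic function of (geometry, resolution).
    """
    if resolution < 16:
        raise ValueError(f"resolution {resolution} below the supported minimum 16")
    R = geometry.membrane_radius
    dx = 2.0 * R / resolution
    n_lead = int(math.ceil(geometry.lead_length / dx)) if geometry.lead_length > 0 else 0
    nx = resolution + 2 * n_lead
    ny = resolution
    x0 = -R - n_lead * dx
    x = x0 + dx * (np.arange(nx) + 0.5)
    y = -R + dx * (np.arange(ny) + 0.5)
    X, Y = np.meshgrid(x, y, indexing="ij")

    in_disc = X**2 + Y**2 < R**2
    if geometry.planform == "disc":
        membrane = in_disc
        half_w = 0.5 * geometry.port_width
        in_strip = np.abs(Y) < half_w
        # leads span from the domain edge to the disc rim; including the sliver
        # between |x| = sqrt(R²−y²) and |x| = R keeps lead and disc connected
        lead = in_strip & ~in_disc & ((X < 0) | (X > 0))
        lead &= np.abs(X) <= R + n_lead * dx
        interior = membrane | lead
    elif geometry.planform == "empty":
        membrane = np.zeros_like(in_disc)
        interior = np.zeros_like(in_disc)
    else:  # user polygon
        inside = _inside_polygon(geometry.planform, X, Y)  # type: ignore[arg-type]
        membrane = in_disc & inside
        interior = inside

    inlet = np.zeros_like(interior)
    outlet = np.zeros_like(interior)
    if interior.any():
        inlet[0, :] = interior[0, :]
        outlet[-1, :] = interior[-1, :]

    return StructuredGrid(
        geometry=geometry,
        nx=nx,
        ny=ny,
        cell_size=dx,
        x=x,
        y=y,
        interior_mask=interior,
        membrane_mask=membrane,
        inlet_mask=inlet,
        outlet_mask=outlet,
    )
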