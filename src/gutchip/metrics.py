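"""Reduction of solution fields to membrane dosimetry summaries, and the
0-D mass-balance model of serially connected devices.

"Whole area" for the shear hot-spot fraction means the membrane area: the
cell-bearing surface is where shear dosimetry matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MembraneMetrics",
    "DeviceSpec",
    "DeviceChain",
    "area_average",
    "area_fraction_above",
    "chain_devices",
    "membrane_metrics",
]


def area_average(field_values: np.ndarray, mask: np.ndarray) -> float:
    """Area-weighted mean of a cell field over a mask (uniform square cells)."""
    if not mask.any():
        raise ValueError("empty mask: area average undefined")
    return float(np.mean(field_values[mask]))


def area_fraction_above(field_values: np.ndarray, mask: np.ndarray, threshold: float) -> float:
    """Area-weighted fraction of masked cells strictly above ``threshold``."""
    if not mask.any():
        raise ValueError("empty mask: area fraction undefined")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return float(np.mean(field_values[mask] > threshold))


@dataclass(frozen=True)
class MembraneMetrics:
    """Summary dosimetry numbers at the membrane."""

    mean_shear: float  # Pa
    max_shear: float  # Pa
    fraction_above: Mapping[float, float]  # threshold (Pa) → area fraction
    min_oxygen: float | None = None  # mol/m³
    outlet_oxygen: float | None = None  # mol/m³


def membrane_metrics(flow, oxygen=None, thresholds: Sequence[float] = (2e-3,)) -> MembraneMetrics:
    """Reduce a flow (and optionally oxygen) solution to membrane summaries."""
    mask = flow.grid.membrane_mask
    frac = {t: area_fraction_above(flow.wall_shear, mask, t) for t in thresholds}
    min_o2 = outlet_o2 = None
    if oxygen is not None:
        min_o2 = oxygen.min_membrane
        outlet_o2 = oxygen.outlet_mixed_cup
    return MembraneMetrics(
        mean_shear=area_average(flow.wall_shear, mask),
        max_shear=float(np.nanmax(flow.wall_shear[mask])),
        fraction_above=frac,
        min_oxygen=min_o2,
        outlet_oxygen=outlet_o2,
    )


@dataclass(frozen=True)
class DeviceSpec:
    """One perfused device in a serial chain: its membrane sink."""

    wall_flux: float  # mol/(m² s)
    membrane_area: float = 1.1312e-4  # m²
    label: str = ""


@dataclass(frozen=True)
class DeviceChain:
    """Ordered devices sharing one perfusion line at equal flow rate."""

    devices: Sequence[DeviceSpec]
    concentrations: Sequence[tuple[float, float]] = field(default=())  # per-device (inlet, outlet)


def chain_devices(chain: DeviceChain, inlet_concentration: float, flow_rate: float) -> DeviceChain:
    """Propagate the mixed-cup oxygen concentration through the chain.

    Each device consumes J·A from the stream; the designated outlet of
    device k feeds the inlet of device k+1 (the serial hydraulic
    connection of the modular platform).  0-D between devices.
    """
    from .oxygen import mixed_cup_outlet

    if flow_rate <= 0:
        raise ValueError("chain requires a strictly positive flow rate")
    if len(chain.devices) == 0:
        raise ValueError("empty device chain")
    conc = []
    c = inlet_concentration
    for dev in chain.devices:
        c_out = mixed_cup_outlet(c, flow_rate, dev.wall_flux, dev.membrane_area)
        conc.append((c, c_out))
        c = c_out
    return DeviceChain(devices=tuple(chain.devices), concentrations=tuple(conc))
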