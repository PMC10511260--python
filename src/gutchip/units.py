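"""Unit conversions at the package boundary.

All internal computation is in SI (m, s, mol, Pa, kg).  Human-facing
laboratory units (μl/min, mPa, cm², hours, days, nmol/min/10⁶ cells) are
converted exactly once, on the way in or out, by the helpers here.
"""

from __future__ import annotations

__all__ = [
    "ul_min_to_m3_s",
    "m3_s_to_ul_min",
    "pa_to_mpa",
    "mpa_to_pa",
    "cm2_to_m2",
    "m2_to_cm2",
    "hours",
    "consumption_to_si",
    "consumption_from_si",
    "density_per_cm2_to_per_m2",
]

_SECONDS_PER_MIN = 60.0
_SECONDS_PER_HOUR = 3600.0

#: hours per supported duration unit
_TIME_UNITS_H = {
    "s": 1.0 / 3600.0,
    "sec": 1.0 / 3600.0,
    "min": 1.0 / 60.0,
    "h": 1.0,
    "hr": 1.0,
    "hour": 1.0,
    "hours": 1.0,
    "d": 24.0,
    "day": 24.0,
    "days": 24.0,
}


def ul_min_to_m3_s(q_ul_min: float) -> float:
    """Volumetric flow rate: μl/min → m³/s."""
    return q_ul_min * 1e-9 / _SECONDS_PER_MIN


def m3_s_to_ul_min(q_m3_s: float) -> float:
    return q_m3_s * _SECONDS_PER_MIN * 1e9


def pa_to_mpa(tau_pa: float) -> float:
    """Stress: Pa → mPa (the scale shear is reported on here)."""
    return tau_pa * 1e3


def mpa_to_pa(tau_mpa: float) -> float:
    return tau_mpa * 1e-3


def cm2_to_m2(a_cm2: float) -> float:
    return a_cm2 * 1e-4


def m2_to_cm2(a_m2: float) -> float:
    return a_m2 * 1e4


def hours(value: float | str, unit: str | None = None) -> float:
    """Normalize a duration to hours.

    Accepts either ``hours(14, "d")`` or a string ``hours("14 d")``; a bare
    number is taken to be hours already.
    """
    if isinstance(value, str):
        parts = value.split()
        if len(parts) != 2:
            raise ValueError(f"cannot parse duration {value!r}; expected '<number> <unit>'")
        value, unit = float(parts[0]), parts[1]
    if unit is None:
        return float(value)
    try:
        return float(value) * _TIME_UNITS_H[unit.lower()]
    except KeyError:
        raise ValueError(f"unsupported time unit {unit!r}; known: {sorted(_TIME_UNITS_H)}") from None


def consumption_to_si(rate_nmol_min_per_1e6_cells: float) -> float:
    """Per-cell O₂ consumption: nmol/min per 10⁶ cells → mol/s per cell."""
    return rate_nmol_min_per_1e6_cells * 1e-9 / _SECONDS_PER_MIN / 1e6


def consumption_from_si(rate_mol_s_per_cell: float) -> float:
    """Inverse of :func:`consumption_to_si` (lossless round-trip)."""
    return rate_mol_s_per_cell * 1e9 * _SECONDS_PER_MIN * 1e6


def density_per_cm2_to_per_m2(density_per_cm2: float) -> float:
    """Cell seeding density: cells/cm² → cells/m²."""
    return density_per_cm2 * 1e4
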