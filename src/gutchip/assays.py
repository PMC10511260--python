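"""Epithelial barrier-function assay reduction: TEER and apparent permeability.

TEER (trans-epithelial electrical resistance) from chopstick-electrode
readings:

    TEER = (mean(R_measured) − R_blank) · A        [Ω·cm²]

with R_blank measured on a collagen-coated insert without cells and A the
nominal membrane area (1.131 cm²).

Apparent permeability of a FITC-dextran tracer from plate-reader
fluorescence:

    P_app = (dQ/dt) / (C₀ · A)                     [cm/s]

where dQ is the amount transported to the basal compartment over the
incubation time dt (default 12 600 s), C₀ the donor concentration
(default 1 mg/ml) and A the membrane area.  dQ is recovered from the
blank-subtracted, replicate-averaged basal fluorescence through a linear
calibration curve fitted to a two-fold serial-dilution ladder
(50 → 0.78 μg/ml), times the basal compartment volume (default 750 μl,
the pipetted basal medium volume).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TeerMeasurement",
    "PermeabilityAssay",
    "CalibrationCurve",
    "compute_teer",
    "fit_calibration",
    "compute_papp",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TeerMeasurement:
    """Raw chopstick-electrode resistances for one insert."""

    resistance_readings: Sequence[float]  # Ω, ≥1 replicate (typically 3)
    blank_resistance: float  # Ω
    membrane_area: float = 1.131  # cm²

    def __post_init__(self) -> None:
        if len(self.resistance_readings) < 1:
            raise ValueError("at least one resistance reading required")
        if any(r <= 0 for r in self.resistance_readings):
            raise ValueError("resistance readings must be positive")
        if self.membrane_area <= 0:
            raise ValueError("membrane area must be positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """Serial-dilution fluorescence ladder and its linear fit."""

    concentrations: Sequence[float]  # μg/ml
    signals: Sequence[float]  # a.u.
    slope: float | None = None  # a.u. per μg/ml
    intercept: float | None = None  # a.u.
    r_squared: float | None = None
    stderr: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.size < 3:
            raise ValueError("calibration needs at least 3 points")
        if np.any(c <= 0):
            raise ValueError("calibration concentrations must be strictly positive")
        if np.unique(c).size != c.size:
            raise ValueError("calibration concentrations must be distinct")

    @property
    def fitted(self) -> bool:
        return self.slope is not None

    def inverse(self, signal: float) -> float:
        """Concentration (μg/ml) from a blank-subtracted signal.

        Refuses extrapolation beyond 1.2× the top of the ladder.
        """
        if not self.fitted:
            raise ValueError("calibration curve has not been fitted")
        conc = (signal - self.intercept) / self.slope
        cmax = 1.2 * float(np.max(self.concentrations))
        if conc > cmax:
            log.error("signal maps to %.3g μg/ml, beyond 1.2× the ladder top (%.3g)", conc, cmax)
            raise ValueError(
                f"signal outside the calibrated range: {conc:.3g} μg/ml > {cmax:.3g} μg/ml"
            )
        return conc


@dataclass(frozen=True)
class PermeabilityAssay:
    """Raw inputs of one FITC-dextran transport measurement."""

    basal_fluorescence_readings: Sequence[float]  # a.u., duplicates typical
    blank_fluorescence: float  # a.u., fresh-medium background
    calibration: CalibrationCurve
    incubation_time: float = 12_600.0  # s (3.5 h)
    initial_concentration: float = 1.0  # mg/ml in the apical (donor) compartment
    membrane_area: float = 1.131  # cm²
    basal_volume_ml: float = 0.75  # ml of acceptor medium

    def __post_init__(self) -> None:
        if len(self.basal_fluorescence_readings) < 1:
            raise ValueError("at least one basal fluorescence reading required")
        if self.incubation_time <= 0:
            raise ValueError("incubation time must be positive")
        if self.initial_concentration <= 0 or self.membrane_area <= 0 or self.basal_volume_ml <= 0:
            raise ValueError("donor concentration, area and basal volume must be positive")


def compute_teer(measurement: TeerMeasurement) -> float:
    """Blank-subtracted, area-normalized epithelial resistance (Ω·cm²).

    Replicates are averaged; a mean reading below the blank signals a
    failed layer and returns a negative value with a warning rather than
    raising.
    """
    mean_r = float(np.mean(np.asarray(measurement.resistance_readings, dtype=float)))
    teer = (mean_r - measurement.blank_resistance) * measurement.membrane_area
    if mean_r < measurement.blank_resistance:
        warnings.warn(
            f"mean reading {mean_r:.1f} Ω below blank {measurement.blank_resistance:.1f} Ω: "
            "negative TEER indicates a failed or absent cell layer",
            stacklevel=2,
        )
    return teer


def fit_calibration(curve: CalibrationCurve) -> CalibrationCurve:
    """Ordinary least-squares line signal = slope·conc + intercept."""
    c = np.asarray(curve.concentrations, dtype=float)
    s = np.asarray(curve.signals, dtype=float)
    if c.size != s.size:
        raise ValueError("concentrations and signals differ in length")
    res = stats.linregress(c, s)
    return replace(
        curve,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr=float(res.stderr),
    )


def compute_papp(assay: PermeabilityAssay) -> float:
    """Apparent permeability (cm/s) from one transport assay.

    Blank-subtract, average replicate readings, invert the calibration to
    the basal concentration, convert to the transported amount through the
    basal volume, and normalize by time, donor concentration and area.
    A signal at or below the blank yields P_app = 0 with a warning.
    """
    if not assay.calibration.fitted:
        raise ValueError("calibration curve must be fitted before computing P_app")
    signal = float(np.mean(np.asarray(assay.basal_fluorescence_readings, dtype=float)))
    net = signal - assay.blank_fluorescence
    if net <= 0:
        warnings.warn("basal signal does not exceed the blank: returning P_app = 0", stacklevel=2)
        return 0.0
    conc_ug_ml = assay.calibration.inverse(net)
    if conc_ug_ml < 0:
        warnings.warn("calibrated concentration below zero: returning P_app = 0", stacklevel=2)
        return 0.0
    dq_ug = conc_ug_ml * assay.basal_volume_ml  # μg transported
    c0_ug_cm3 = assay.initial_concentration * 1000.0  # mg/ml → μg/cm³
    return (dq_ug / assay.incubation_time) / (c0_ug_cm3 * assay.membrane_area)
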