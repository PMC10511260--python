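"""TEER and apparent-permeability reductions, calibration fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutchip import (
    CalibrationCurve,
    PermeabilityAssay,
    TeerMeasurement,
    compute_papp,
    compute_teer,
    fit_calibration,
)


def _line_curve(slope=2.0, intercept=5.0):
    conc = 50.0 / 2.0 ** np.arange(7)
    return CalibrationCurve(concentrations=tuple(conc), signals=tuple(slope * conc + intercept))


class TestTeer:
    def test_hand_value(self):
        """(700 − 125) × 1.131 ≈ 650 Ω·cm², the static-culture scale."""
        m = TeerMeasurement((700.0, 700.0, 700.0), 125.0, 1.131)
        assert compute_teer(m) == pytest.approx(650.3, abs=0.05)

    def test_reading_equal_blank_zero(self):
        assert compute_teer(TeerMeasurement((125.0,), 125.0)) == 0.0

    def test_identity_case(self):
        assert compute_teer(TeerMeasurement((432.0,), 0.0, 1.0)) == 432.0

    def test_below_blank_warns_returns_negative(self):
        with pytest.warns(UserWarning, match="below blank"):
            teer = compute_teer(TeerMeasurement((100.0,), 125.0))
        assert teer < 0

    @given(perm=st.permutations([640.0, 700.0, 760.0]))
    @settings(max_examples=6, deadline=None)
    def test_replicate_permutation_invariance(self, perm):
        ref = compute_teer(TeerMeasurement((640.0, 700.0, 760.0), 125.0))
        assert compute_teer(TeerMeasurement(tuple(perm), 125.0)) == pytest.approx(ref, rel=1e-14)


class TestCalibration:
    def test_exact_line_recovered(self):
        fit = fit_calibration(_line_curve(slope=2.0, intercept=5.0))
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(5.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_twofold_ladder_bottom(self):
        """Six two-fold dilutions from 50 μg/ml end at 0.78125 μg/ml."""
        conc = np.asarray(_line_curve().concentrations)
        assert conc.min() == pytest.approx(50.0 / 2**6, rel=1e-12)
        assert conc.min() == pytest.approx(0.78125)

    def test_inverse_round_trip(self):
        fit = fit_calibration(_line_curve(slope=3.0, intercept=0.0))
        assert fit.inverse(3.0 * 12.5) == pytest.approx(12.5, rel=1e-12)

    def test_refuses_extrapolation(self):
        fit = fit_calibration(_line_curve(slope=1.0, intercept=0.0))
        with pytest.raises(ValueError, match="outside the calibrated range"):
            fit.inverse(1.3 * 50.0)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            CalibrationCurve(concentrations=(1.0, 1.0, 1.0), signals=(1.0, 2.0, 3.0))
        with pytest.raises(ValueError):
            CalibrationCurve(concentrations=(1.0, 2.0), signals=(1.0, 2.0))

    def test_unfitted_curve_cannot_invert(self):
        with pytest.raises(ValueError, match="not been fitted"):
            _line_curve().inverse(10.0)


class TestPapp:
    def _assay(self, net_signal, slope=1.0):
        cal = fit_calibration(_line_curve(slope=slope, intercept=0.0))
        return PermeabilityAssay(
            basal_fluorescence_readings=(net_signal + 10.0,),
            blank_fluorescence=10.0,
            calibration=cal,
            incubation_time=12_600.0,
            initial_concentration=1.0,
            membrane_area=1.131,
            basal_volume_ml=0.75,
        )

    def test_hand_value(self):
        """12.6 μg over 12 600 s at C₀ = 1 mg/ml, A = 1.131 cm² → 8.84×10⁻⁷ cm/s."""
        conc = 12.6 / 0.75  # μg/ml in the basal compartment
        papp = compute_papp(self._assay(net_signal=conc))
        assert papp == pytest.approx(8.84e-7, rel=1e-3)

    def test_zero_transport_zero_papp(self):
        with pytest.warns(UserWarning):
            assert compute_papp(self._assay(net_signal=0.0)) == 0.0

    def test_linearity_in_amount(self):
        p1 = compute_papp(self._assay(net_signal=8.0))
        p2 = compute_papp(self._assay(net_signal=16.0))
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_replicate_permutation_invariance(self):
        cal = fit_calibration(_line_curve(slope=1.0, intercept=0.0))
        a = PermeabilityAssay((15.0, 25.0), 10.0, cal)
        b = PermeabilityAssay((25.0, 15.0), 10.0, cal)
        assert compute_papp(a) == compute_papp(b)
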