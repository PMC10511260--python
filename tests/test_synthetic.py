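"""Synthetic generators: round-trips, reproducibility, manufactured verification."""

import numpy as np
import pytest

from gutchip import (
    SyntheticAssayTruth,
    compute_papp,
    compute_teer,
    fit_calibration,
    gen_permeability_assay,
    gen_teer_series,
)
from gutchip.synthetic import (
    manufactured_flow_case,
    manufactured_oxygen_case,
    run_manufactured_flow,
    run_manufactured_oxygen,
    run_manufactured_slice,
)
from gutchip.geometry import ChamberGeometry, make_grid
from gutchip.units import ul_min_to_m3_s
from tests.conftest import l2_orders
import dataclasses
import math


def _recover_papp(truth):
    assay = gen_permeability_assay(truth)
    assay = dataclasses.replace(assay, calibration=fit_calibration(assay.calibration))
    return compute_papp(assay)


class TestAssayGenerators:
    def test_papp_noiseless_round_trip(self):
        truth = SyntheticAssayTruth(true_papp=2.0e-6, noise_sd=0.0, seed=1)
        assert _recover_papp(truth) == pytest.approx(truth.true_papp, rel=1e-12)

    def test_papp_zero_truth_gives_blank_signals(self):
        truth = SyntheticAssayTruth(true_papp=0.0, noise_sd=0.0, seed=1)
        assay = gen_permeability_assay(truth)
        assert np.allclose(assay.basal_fluorescence_readings, assay.blank_fluorescence)

    def test_papp_noisy_single_draw_recovery(self):
        truth = SyntheticAssayTruth(true_papp=2.0e-6, noise_sd=0.02, seed=7)
        assert _recover_papp(truth) == pytest.approx(truth.true_papp, rel=0.05)

    def test_papp_recovery_within_noise_across_seeds(self):
        """100 seeded assays at 2% noise recover the injected P_app within 3σ."""
        truth0 = SyntheticAssayTruth(true_papp=2.0e-6, noise_sd=0.02)
        recovered = np.array(
            [_recover_papp(dataclasses.replace(truth0, seed=s)) for s in range(100)]
        )
        rel_err = recovered / truth0.true_papp - 1.0
        # each draw within 3× the injected fractional noise of the truth
        assert np.all(np.abs(rel_err) < 3 * truth0.noise_sd)
        assert abs(rel_err.mean()) < 0.01

    def test_teer_noiseless_round_trip(self):
        truth = SyntheticAssayTruth(true_teer=650.0, noise_sd=0.0, seed=3)
        assert compute_teer(gen_teer_series(truth)) == pytest.approx(650.0, rel=1e-12)

    def test_teer_zero_truth_reads_blank(self):
        m = gen_teer_series(SyntheticAssayTruth(true_teer=0.0, noise_sd=0.0, seed=3))
        assert np.allclose(m.resistance_readings, m.blank_resistance)

    def test_teer_mean_recovery_many_seeds(self):
        """Mean of 100 noisy triplicate reductions lands within 1% of truth."""
        truth0 = SyntheticAssayTruth(true_teer=650.0, noise_sd=0.03)
        vals = [
            compute_teer(gen_teer_series(dataclasses.replace(truth0, seed=s)))
            for s in range(100)
        ]
        assert np.mean(vals) == pytest.approx(650.0, rel=0.01)

    def test_generators_are_pure_in_seed(self):
        t = SyntheticAssayTruth(noise_sd=0.05, seed=11)
        a, b = gen_permeability_assay(t), gen_permeability_assay(t)
        assert a.basal_fluorescence_readings == b.basal_fluorescence_readings
        assert a.calibration.signals == b.calibration.signals
        c = gen_permeability_assay(dataclasses.replace(t, seed=12))
        assert a.basal_fluorescence_readings != c.basal_fluorescence_readings


class TestManufacturedFlow:
    def test_linear_case_exact(self):
        geom = ChamberGeometry(
            planform=[(-0.009, -0.005), (0.009, -0.005), (0.009, 0.005), (-0.009, 0.005)],
            lead_length=0.0,
        )
        for res in (32, 64):
            r = run_manufactured_flow(manufactured_flow_case("linear"), make_grid(geom, res))
            assert r["max_error"] < 1e-10

    def test_constant_case_zero_velocity(self):
        geom = ChamberGeometry(membrane_area=math.pi, lead_length=0.0)
        r = run_manufactured_flow(manufactured_flow_case("constant"), make_grid(geom, 32))
        assert r["max_error"] < 1e-12

    def test_dipole_convergence_order(self):
        """Source/sink potential on the disc: L2 order ≥ 1.8 under refinement."""
        geom = ChamberGeometry(membrane_area=math.pi, lead_length=0.0)
        case = manufactured_flow_case("dipole")
        errs = [run_manufactured_flow(case, make_grid(geom, res))["l2_error"] for res in (32, 64, 128)]
        assert np.mean(l2_orders(errs)) >= 1.8


class TestManufacturedOxygen:
    def test_constant_field(self):
        r = run_manufactured_oxygen(manufactured_oxygen_case("constant"), 24)
        assert r["max_error"] < 1e-12

    def test_central_convergence_order(self):
        case = manufactured_oxygen_case("diffusion")
        errs = [run_manufactured_oxygen(case, n, scheme="central")["l2_error"] for n in (16, 32, 64)]
        assert np.mean(l2_orders(errs)) >= 1.8

    def test_upwind_convergence_order(self):
        case = manufactured_oxygen_case("advection")
        errs = [
            run_manufactured_oxygen(case, n, velocity=50.0, scheme="upwind")["l2_error"]
            for n in (16, 32, 64)
        ]
        assert np.mean(l2_orders(errs)) >= 1.0

    def test_slice_central_convergence_order(self):
        errs = [run_manufactured_slice(n, scheme="central")["l2_error"] for n in (8, 16, 32)]
        assert np.mean(l2_orders(errs)) >= 1.8

    def test_slice_upwind_convergence_order(self):
        q = ul_min_to_m3_s(30.0)
        errs = [run_manufactured_slice(n, scheme="upwind", flow_rate=q)["l2_error"] for n in (8, 16, 32)]
        assert np.mean(l2_orders(errs)) >= 1.0
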