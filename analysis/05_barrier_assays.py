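#!/usr/bin/env python
"""Barrier-function assay reduction rehearsed on synthetic cohorts.

Generates seeded synthetic static and perfused cohorts (quadruplicate)
with ground-truth TEER and P_app at the scales the device experiments
report — static TEER ≈ 650 Ω·cm² vs perfused ≈ 190 Ω·cm², with the
perfused layer correspondingly more permeable — pushes them through the
calibration-fit → blank-subtract → reduce pipeline, and verifies the
recovered group means.  Writes results/barrier_assays.csv.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from gutchip import (
    SyntheticAssayTruth,
    compute_papp,
    compute_teer,
    fit_calibration,
    gen_permeability_assay,
    gen_teer_series,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2023
N_REPLICATES = 4
NOISE_SD = 0.03

#: ground truth per group: (TEER Ω·cm², P_app cm/s)
GROUPS = {"static": (650.0, 8.0e-7), "perfused": (190.0, 2.0e-6)}


def main() -> None:
    rows = []
    for gi, (g, (teer_true, papp_true)) in enumerate(GROUPS.items()):
        for rep in range(N_REPLICATES):
            truth = SyntheticAssayTruth(
                true_papp=papp_true,
                true_teer=teer_true,
                noise_sd=NOISE_SD,
                seed=SEED + 100 * rep + 17 * gi,
            )
            teer = compute_teer(gen_teer_series(truth))
            assay = gen_permeability_assay(truth)
            assay = dataclasses.replace(assay, calibration=fit_calibration(assay.calibration))
            papp = compute_papp(assay)
            rows.append(
                {
                    "group": g,
                    "replicate": rep + 1,
                    "teer_ohm_cm2": teer,
                    "papp_cm_s": papp,
                    "true_teer_ohm_cm2": teer_true,
                    "true_papp_cm_s": papp_true,
                }
            )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "barrier_assays.csv", index=False, lineterminator="\n")
    print(df.to_string(index=False))
    summary = df.groupby("group")[["teer_ohm_cm2", "papp_cm_s"]].agg(["mean", "std"])
    print("\n", summary.to_string())
    for g, (teer_true, papp_true) in GROUPS.items():
        m = df[df.group == g]
        assert abs(m.teer_ohm_cm2.mean() / teer_true - 1) < 0.1
        assert abs(m.papp_cm_s.mean() / papp_true - 1) < 0.1
    print(
        "\nRecovered group means agree with the injected truths within 10%: "
        "the reduction pipeline preserves the static-vs-perfused contrast "
        "(lower TEER, higher P_app under flow)."
    )


if __name__ == "__main__":
    main()
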