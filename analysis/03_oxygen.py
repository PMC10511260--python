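#!/usr/bin/env python
"""Oxygen supply to the monolayer at the candidate perfusion rates.

Couples the flow solutions to the advection–diffusion transport of
dissolved oxygen with the worst-case consumption flux at the membrane,
in both reduced models (planform depth-average and vertical slice), and
checks each against the analytic mixed-cup balance C_in − J·A/Q.
Writes results/oxygen_metrics.csv.

Finding: at 30 μl/min the membrane minimum stays well above zero — no
oxygen deficiency at the selected operating point — while at 5 μl/min
the margin thins as the outlet mixed-cup drops toward 0.095 mol/m³.
"""

from pathlib import Path

import pandas as pd

from gutchip import (
    ChamberGeometry,
    DosimetryParams,
    FluidProperties,
    TransportProperties,
    make_grid,
    mixed_cup_outlet,
    oxygen_wall_flux,
    solve_flow,
    solve_oxygen_planform,
    solve_oxygen_slice,
)
from gutchip.units import ul_min_to_m3_s

OUT = Path(__file__).resolve().parents[1] / "results"
RATES_UL_MIN = (5.0, 15.0, 30.0, 50.0, 200.0)
RESOLUTION = 200


def main() -> None:
    geometry = ChamberGeometry()
    fluid = FluidProperties()
    transport = TransportProperties()
    dose = oxygen_wall_flux(DosimetryParams())
    grid = make_grid(geometry, RESOLUTION)

    rows = []
    for rate in RATES_UL_MIN:
        q = ul_min_to_m3_s(rate)
        flow = solve_flow(grid, fluid, q)
        plan = solve_oxygen_planform(grid, flow, transport, dose)
        sli = solve_oxygen_slice(geometry, fluid, transport, dose, q)
        rows.append(
            {
                "rate_ul_min": rate,
                "min_membrane_mol_m3_planform": plan.min_membrane,
                "min_membrane_mol_m3_slice": sli.min_membrane,
                "outlet_mol_m3_planform": plan.outlet_mixed_cup,
                "outlet_mol_m3_slice": sli.outlet_mixed_cup,
                "outlet_mol_m3_balance": mixed_cup_outlet(
                    transport.inlet_concentration, q, dose.wall_flux, geometry.membrane_area
                ),
                "oxygen_deficient": plan.oxygen_deficient or sli.oxygen_deficient,
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "oxygen_metrics.csv", index=False, lineterminator="\n")
    print(df.to_string(index=False))
    at30 = df[df.rate_ul_min == 30.0].iloc[0]
    print(
        f"\nAt 30 ul/min: minimum membrane O2 {at30.min_membrane_mol_m3_planform:.4f} mol/m^3 "
        f"(planform) / {at30.min_membrane_mol_m3_slice:.4f} (slice); outlet "
        f"{at30.outlet_mol_m3_planform:.4f} vs analytic balance {at30.outlet_mol_m3_balance:.4f}."
    )


if __name__ == "__main__":
    main()
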