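# Methods

## Problem and scope

A millifluidic gut-on-a-chip perfuses the apical side of a Transwell-like
insert on which a Caco-2 epithelial monolayer grows. The design
questions are (i) which flow rate delivers a membrane-averaged wall
shear above the ≈ 0.67 mPa level associated with epithelial
differentiation without exposing much of the layer to damaging peaks,
(ii) whether the perfusion supplies enough dissolved oxygen against the
worst-case consumption of the growing monolayer, alone and in serially
connected devices, and (iii) how the barrier-function readouts (TEER,
FITC-dextran apparent permeability) are reduced from raw instrument
readings. `gutchip` implements all three as a tested library plus
narrative analysis drivers.

## Flow model

**Reduction.** The chamber is 0.5 mm high over a ≈ 12 mm planform
(aspect ratio ≈ 0.04) and the port Reynolds number at the 30 μl/min
operating point is ≈ 0.6. In this regime the stationary incompressible
Navier–Stokes problem reduces to the Hele-Shaw/lubrication form: a
Laplace-type equation for pressure, ∇·(h³/(12μ)∇p) = 0, with the
depth-averaged velocity ū = −(h²/12μ)∇p and the no-slip top/bottom
walls absorbed into the parabolic depth profile. Solving the
depth-averaged equations instead of the volumetric ones is the main
engineering reduction in this package and the reason the absolute shear
numbers carry a wide tolerance (below). The solver warns when Re ≥ 1 or
when the aspect ratio leaves the thin-film regime.

**Wall shear.** τ = μ|∂u/∂z| at the membrane wall = 6μ|ū|/h, reported
as a magnitude; membrane averages are area-weighted over the membrane
mask only. The shear scales exactly linearly with Q (Stokes), which the
tests assert to solver tolerance; the plane-Poiseuille strip limit
6μQ/(wh²) serves as a closed-form oracle (matched within 0.4% at
resolution 200).

**Geometry.** The device's interior 3-D chamber shape is not published.
The default planform is the minimal shape consistent with the device
description: the membrane disc (radius √(A/π) ≈ 6.00 mm from A =
1.1312 cm²) plus two straight rectangular port leads (width 0.8 mm,
admissible 0.5–1 mm; length 2 mm) attached at diametrically opposite rim
points. Ports are finite-width boundary segments, never point sources —
point ports make the wall shear diverge and area-fraction statements
untestable. A cell belongs to the membrane iff its centre lies in the
disc; grids are deterministic in (geometry, resolution).

**Discretization.** Cell-centred finite volumes on a uniform square
grid (default resolution: 200 cells across the membrane diameter,
≈ 32 000 unknowns — converged to < 1% in the reported metrics and
solving in well under a second), 5-point two-point-flux stencil, direct
sparse LU with an ILU-preconditioned GMRES fallback at relative
tolerance 10⁻¹⁰. The port boundary conditions are uniform influx across
the inlet segment and uniform outflux across the outlet segment; the
resulting pure-Neumann system is closed by replacing one balance row
with a pin (exact for compatible data, since the dropped row is the
negative sum of the others — a mean-constraint Lagrange row was tried
first and discarded because its dense row destroys sparse-LU fill-in),
after which the pressure is re-gauged so the outlet-port mean is 0 Pa.
Discrete conservation holds in every cell to ≈ 10⁻¹² of the through-flow.
Verification: a linear pressure field is reproduced to machine
precision; a smooth source/sink ("dipole") potential on the disc
converges at observed L2 order ≈ 2.0.

## Oxygen model

**Worst case.** Cells are oxygenated only from the apical chamber, at
maximum density from day 0: the wall flux is J = q_cell·σ·d with q_cell
the basal per-cell uptake (2.1 nmol/min/10⁶ cells), σ the seeding
density (5×10⁴ cells/cm²) and d = duration/division time the doubling
count (336 h / 80 h = 4.2), giving J = 7.35×10⁻⁸ mol/(m² s). The growth
factor enters linearly (σ·d), not geometrically (σ·2^d): the linear
factor is the one consistent with the stated flux value, and it reads
naturally as a linear-growth bound on the areal cell density; a
geometric factor would give ≈ 3×10⁻⁷ mol/(m² s) and anoxia at every
tabulated flow rate. No Michaelis–Menten kinetics, no time dependence,
no basal oxygen path.

**Two reduced models.** (a) *Planform*: depth-averaged
advection–diffusion on the flow grid, the membrane flux as a volumetric
sink J/h over membrane cells — resolves the lateral distribution and
the slow near-rim zones, averages the vertical boundary layer away.
(b) *Slice*: vertical x–z section of an equal-area rectangle (length =
membrane diameter 12 mm, effective width A/L ≈ 9.4 mm, both
configurable) with the plane-Poiseuille profile u(z) = 6ū(z/h)(1−z/h)
and the constant flux on the bottom wall — resolves the developing
Graetz-type depletion layer the planform model cannot see. Boundary
conditions in both: inlet Dirichlet at the saturation concentration
0.195 mol/m³, advective outflow, zero-flux walls; the bulk reaction term
is zero (all consumption is at the membrane). Advection is upwinded
when the grid Péclet exceeds 2 (the default "auto" scheme; a requested
central scheme is switched with a logged warning). Negative
concentrations are never clamped: the field is flagged
`oxygen_deficient` and reported.

**Checks.** The discrete global balance inflow − outflow − J·A closes
to ≈ 10⁻¹²; both models match the analytic mixed-cup outlet C_in − J·A/Q
(0.1784 mol/m³ at 30 μl/min) within well under 1%, and each other within
0.1%. Manufactured solutions (boundary-compatible trigonometric fields
with matching sources) give observed L2 orders ≈ 2.0 (central) and ≥ 1
(upwind) for both models. The serial-chain model is purely 0-D
(mixed-cup per device); it reproduces the two-device series used to
demonstrate modular connection.

## Barrier assays

TEER = (mean reading − blank)·area, with the blank measured on a
coated cell-free insert and area 1.131 cm²; replicates (typically
triplicate) reduce by arithmetic mean; a mean below blank returns a
negative value with a warning (layer failure is a result, not a crash).
P_app = (dQ/dt)/(C₀·A) with dt = 12 600 s, C₀ = 1 mg/ml, A = 1.131 cm²;
dQ comes from the blank-subtracted, duplicate-averaged basal
fluorescence through an ordinary least-squares calibration line fitted
on the raw two-fold dilution ladder 50 → 0.78125 μg/ml (fluorescence is
linear in this range, so no log transform), times the basal compartment
volume. That volume is not part of the printed formula and defaults to
0.75 ml, the pipetted basal medium volume; it is configurable. The
inverse calibration refuses extrapolation beyond 1.2× the ladder top.

## Synthetic data

The generators emulate: a plate reader measuring the calibration ladder
(net, blank-subtracted signals) and raw duplicate basal readings
consistent with an injected true P_app; and triplicate chopstick
resistance readings consistent with an injected true TEER. Noise is
multiplicative Gaussian on signals, truncated at zero, with default
fractional SD 2–3% (typical plate-reader/voltohmmeter repeatability);
default truths 2×10⁻⁶ cm/s and 650 Ω·cm², the scales the device
experiments report. All generators are pure functions of (truth, seed).
What passing round-trip tests show is that the *reduction pipeline* is
correct and unbiased under instrument-like noise; they say nothing
about biological variability, edge leaks, temperature drift of the
electrodes, or tracer binding — real-data effects the generator does
not model.

## Known limitations

* **Planform sensitivity of absolute shear.** On the minimal
  disc-plus-leads planform the entire flow enters the membrane region
  through a 0.8 mm mouth at the rim, so the membrane average at
  30 μl/min computes to 1.48 mPa — a factor 1.7 above the 0.855 mPa the
  volumetric simulation of the actual (unpublished) chamber reports, and
  the port jets keep ≈ 13% (grid-converged) of the membrane above 2 mPa
  rather than < 10%. A closed-form point-port estimate reproduces this:
  shear exceeds 2 mPa within r\* = 6μQ/(πh²·2 mPa) ≈ 1.95 mm of each
  port mouth, and two such half-discs are ≈ 11–13% of the membrane.
  Both discrepancies shrink if the real chamber is wider than the
  membrane or routes the ports above the membrane plane; flow-rate
  *ratios*, thresholds crossings and all oxygen quantities are
  insensitive to this geometric uncertainty.
* The depth-averaged shear is a wall magnitude under the local
  Poiseuille closure; within ≈ h of the port mouths the closure itself
  is approximate.
* The oxygen models neglect consumption kinetics (constant J even where
  the local concentration is low), so they are conservative about
  supply but cannot predict partial-uptake adaptation.
* The chain model assumes perfect mixing between devices and equal flow
  through the chain; an optional per-device PDE re-solve is available
  by running the solvers with the previous device's outlet as inlet.
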