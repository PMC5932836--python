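# Methods

`aortohemo` simulates blood flow in synthetic infant aortas and reproduces the
statistical machinery used to validate image-derived CFD hemodynamics against
transthoracic echocardiography (TTE) and cardiac catheterization. This note
records the models, the numerical choices, and what the synthetic setting can
and cannot show about real patient data.

## Lumped outlet model (three-element Windkessel)

Each outlet — brachiocephalic artery (BA), left common carotid (LCCA), left
subclavian (LSA) and descending aorta (DAo) — is terminated by an RCR circuit:
characteristic resistance R1 in series with peripheral resistance R2 ∥
compliance C. Outlet pressure P and flow Q obey

    P + R2·C·dP/dt = (R1 + R2)·Q + R1·R2·C·dQ/dt.

Native units are clinical (mmHg, ml/s, so the published parameter triples are
usable verbatim); SI conversion (1 mmHg = 133.322 Pa) happens only at the 3D
coupling boundary. The packaged defaults are

| outlet | R1 (mmHg·s/ml) | R2 (mmHg·s/ml) | C (ml/mmHg) |
|--------|---------------|---------------|-------------|
| BA     | 0.100         | 2.480         | 0.466       |
| LCCA   | 0.110         | 2.510         | 0.443       |
| LSA    | 0.150         | 2.624         | 0.437       |
| DAo    | 0.120         | 2.118         | 0.421       |

Time integration is backward Euler: with β = R2·C/Δt,

    P[n+1] = ((R1+R2+R1·β)·Q[n+1] − R1·β·Q[n] + β·P[n]) / (1+β).

The update is exact at the steady fixed point P = (R1+R2)·Q and first-order
accurate against a Runge–Kutta reference; both are asserted in tests. Note
the compliance must multiply the dQ/dt term for the equation to be
dimensionally consistent — a published variant of this discretization that
drops the Q[n+1] factor fails to converge to the ODE and is kept out of the
code (a regression test demonstrates the inconsistency).

Initialization: unless overridden, simulations start each outlet at the
steady pressure of the cycle-mean flow, which removes most of the start-up
transient (the relaxation time R2·C ≈ 1 s spans roughly two cardiac cycles,
so a cold start would need many cycles to settle).

## Flow solver

Incompressible Newtonian Navier–Stokes (ρ = 1050 kg/m³, μ = 0.004 Pa·s, no
body force) on a uniform Cartesian staggered (MAC) grid over the voxelized
lumen, with a stair-step immersed wall:

* first-order upwind advection, explicit diffusion;
* pressure projection each step: Poisson equation with homogeneous Neumann
  conditions at walls and the inlet, Dirichlet (Windkessel pressure) at
  outlet faces; the operator is factorized once (sparse LU) per domain;
* no-slip enforced by zeroing velocity components on faces touching solid
  cells (first-order wall treatment);
* inlet velocity: plug profile by default (scaled so the discrete flux
  matches the waveform exactly); a parabolic option exists for analytic
  verification;
* outlet coupling is explicit: the outward flux measured after the
  projection drives one Windkessel step whose pressure becomes the next
  step's Dirichlet value. The identical discrete map is exposed as
  `windkessel.replay`, so any run can be audited offline from its recorded
  flux trace (asserted to round-off in tests).

The time step tracks the advective CFL (target 0.4, adapted every step,
growth-limited) and is capped by the explicit viscous limit ρh²/(6μ) and by
1/200 of the cardiac period so the waveform stays resolved. Post-projection
divergence is monitored every step (direct solve: ~1e-10 s⁻¹ in practice
versus a 1e-6 tolerance).

Verification is by analytic limits rather than comparison with any
particular commercial solver: at 16 cells across the diameter a steady tube
run reproduces the Poiseuille centerline/mean ratio of 2 within 5%, wall
shear 4μQ/(πR³) within 15%, inlet pressure = Windkessel steady value plus
the analytic 8μLQ/(πR⁴) drop within 10%, and global mass conservation to
0.1%. A uniform pressure offset applied to every outlet leaves the velocity
field unchanged to round-off (discrete gauge invariance).

## Synthetic aorta geometry

A parametric stand-in for an image-derived reconstruction: vertical
ascending limb (inlet at the origin, +z), circular-arc arch in the x–z plane,
vertical descending limb, three vertical branch cylinders (BA, LCCA, LSA) at
45°/90°/135° along the arch, and a piecewise-linear radius taper through the
aortic isthmus (AI) to the DAo outlet. An `ai_stenosis_factor` in (0,1]
multiplies the isthmus diameter to emulate coarctation-like narrowing.
Probe planes: mid-ascending (AscAo), the isthmus (AI, just distal to the
arch), and the DAo outlet; reported diameters are equivalent-circle
diameters 2·√(A/π). Wall points carry a quadrant (O/R/L/I; I faces the arch
center, R = −y) and a clinical region tag — the ascending aorta ends at the
BA origin and the arch at the LSA origin, matching anatomical convention
rather than the geometric arc endpoints.

Voxelization samples the implicit solid at cell centers (grid aligned so cap
planes fall on face planes), prunes stray components, and labels inlet/outlet
cap faces; at least 8 cells across the smallest lumen are required (warning
below 10). Surfaces are exported as watertight STL via marching cubes on the
signed distance field; voxel fields as plain-text legacy VTK.

## Hemodynamic read-outs

* **Wall shear stress**: first-order one-sided closure τ = μ·|u_t|/(h/2)
  per wall face, consistent with the stair-step wall. Peak-systolic maps are
  evaluated at the instant of maximum inflow. Extrema exclude faces within
  one cap diameter of any inlet/outlet (boundary-condition artifacts).
* **PSV**: maximum over the cycle of the fastest velocity on the AscAo plane
  (what a TTE Doppler gate reads), cm/s.
* **PSP**: maximum over the cycle of the area-averaged pressure on the AI
  plane (a catheter-like lumped reading), mmHg.
* **Helicity**: localized normalized helicity LNH = u·ω/(|u||ω|) per cell
  (defined 0 where |u| or |ω| < 1e-10 SI); streamlines by fixed-step RK4 on
  the interpolated velocity.

## Virtual cohort

The generator emulates the 25-infant study population. Per case (seeded,
counter-indexed substreams so a cohort can be extended without reshuffling):

* diameters from independent truncated Gaussians matched to the reported
  cohort summary — AscAo 19.2 ± 6.0 mm, AI 12.1 ± 3.5 mm, DAo 10.9 ± 2.6 mm
  (truncated above 3 mm; the inter-site correlation structure of real
  anatomies is not recoverable from summary statistics and is not modeled,
  so occasional mild local bulges occur and are accepted — the marginal
  means stay unbiased);
* branch diameters as fixed fractions of the ascending diameter (BA 0.50,
  LCCA 0.40, LSA 0.42) and segment lengths scaled to it — typical infant
  proportions;
* heart rate uniform in 90–130 bpm; systolic fraction 0.3; inlet waveform a
  half-sine systolic pulse (peak flow π·SV/(2·t_sys)), the standard minimal
  pulsatile shape when the measured waveform is unavailable;
* stroke volume allometric in aortic size with lognormal flow spread,
  SV = 25 ml · (d_AscAo/19.2 mm)^1.5 · exp(N(0, 0.3²)), clamped to 8–55 ml.
  The coupling mirrors how cardiac output and aortic caliber co-scale with
  body size; the spread produces the clinical TTE velocity envelope (bulk
  PSV ≈ 60–230 cm/s, occasional higher jets in small aortas). Fully
  independent SV sampling would produce non-physiologic extremes in small
  aortas, and velocity-preserving SV ∝ area would collapse the PSV spread;
* a distal reference pressure uniform in 60–90 mmHg added to all outlets.
  The RCR constants above, driven by infant-scale flows, produce only
  ~25–45 mmHg by themselves; a downstream reference is the standard way a
  Windkessel reproduces physiologic absolute pressures, and by gauge
  invariance it does not perturb velocities or wall shear;
* measurement noise: additive Gaussian on PSV (SD 11.6 cm/s) and PSP
  (SD 4.4 mmHg) — the reported limits-of-agreement half-widths divided by
  1.96, i.e. noise of the same order as the clinical method differences.

Cohort-scale statistics use the reduced-order pipeline: the aorta as a
lossless junction feeding the four Windkessel outlets (per step, the common
junction pressure and per-outlet flows solve a small linear system), PSP =
last-cycle junction maximum plus the distal reference, PSV = 1.3 × peak plug
velocity (a partially developed profile between plug 1.0 and Poiseuille 2.0).
The full 3D solver fills the same quantities for individual cases; running
25 3D cases is reserved for larger compute budgets.

## Problem sizes used in the tests

Chosen as the smallest sizes at which the asserted properties are clean:
steady tube at h = 1 mm (16 cells across, ~12k fluid cells, seconds);
cohort-mean aorta at h = 0.85 mm (~40k fluid cells, two cardiac cycles,
minutes) for the qualitative localization checks; 25-case cohorts through
the reduced-order pipeline (seconds) for the end-to-end agreement recovery.

## Known limitations

* Rigid walls (no fluid–structure interaction), Newtonian rheology, laminar
  flow without a turbulence model.
* The stair-step wall makes single-face WSS values first-order accurate at
  best; regional statements are meaningful, individual faces noisy.
* The idealized planar arch with a vertical plug inlet localizes the
  peak-systolic WSS maximum at the inner wall of the distal ascending
  aorta / bend entrance (inviscid bend acceleration at the tight arch
  curvature), with the branch ostia and outer arch as secondary hot zones;
  this is stable under grid refinement (checked at two resolutions).
  Patient-derived geometries in the clinical literature — elongated,
  non-planar arches with valve-skewed inflow — more often show the maximum
  on the outer arch wall, and the corresponding localization test is
  deliberately left failing rather than weakened. The low-WSS localization
  (outer/right ascending wall) and the helicity contrast (arch >
  descending) are reproduced.
* Windkessel parameters are the published constants for all cases (the
  study itself used constant parameters); no per-patient identification.
* The synthetic cohort demonstrates that the pipeline and statistics recover
  known ground truth under the configured noise — it cannot validate the
  solver against real patients, which requires patient geometries and
  measurements that were never shared.
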