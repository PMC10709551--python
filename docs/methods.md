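# Methods

## Fluid model and discretization

`willisflow` solves weakly compressible Navier–Stokes flow with a D3Q19
single-relaxation-time (BGK) lattice-Boltzmann method.  The model
assumptions are:

* **Newtonian blood.**  Kinematic viscosity `nu = 4.0e-6 m²/s`
  (dynamic viscosity 4 mPa·s at density 1000 kg/m³).  Shear-thinning is
  neglected; in arteries of millimetre calibre at arterial shear rates
  this is the standard approximation.
* **Rigid walls.**  Vessel diameters are constant in time; flow-mediated
  dilation acts on second-to-minute timescales, longer than the simulated
  few heartbeats.
* **Low Mach number.**  The lattice Mach number `Ma = u_lat·√3` must stay
  small; errors enter at O(Ma²).  `stability_report` flags configurations
  with Ma above a cap (default 0.1).

The relaxation time follows from the discretization,
`tau = 3·nu·dt/dx² + 1/2`; on the reference lattice `dx = 25 µm`,
`dt = 1 µs` this evaluates to 0.5192.  A run at 3 s physical duration and
`dt = 1 µs` schedules exactly 3,000,000 steps.  One step is collide →
stream → wall links → inlet links → outlets; observables are sampled
after boundary resolution.  The production stepper is a fused
numba-compiled kernel verified in the test suite against the separate
numpy operations (`collide_bgk`, `stream`, boundary resolvers) to
rounding.  Everything is double precision and deterministic — there are
no stochastic elements, so no seeds.

**Time-step rule.**  When `dt` is not given it is derived by mapping the
peak inlet speed to a target lattice speed (default 0.04, i.e. Ma ≈ 0.07),
and `tau` follows from the viscosity relation.  At coarse desk
resolutions this places `tau` only slightly above 1/2 (the reference
lattice itself sits at 0.5192); BGK remains stable here because the grid
Reynolds number stays small.  When `dx` changes, `dt` rescales
diffusively (`dt ∝ dx²`) at fixed viscosity so `tau` is preserved.

## Boundary conditions

* **Walls:** halfway bounce-back on the staircase voxel surface.  The
  effective no-slip plane sits half a lattice spacing beyond the last
  fluid site; wall placement is first-order on oblique surfaces, which
  the validation cases compensate for with ≥ 20 sites per diameter.
* **Velocity inlets:** moving-wall (momentum-corrected) bounce-back.
  Each inlet site carries a weight `w = 1 − (1 − d/d_ref)²`, zero at the
  wall and one at the cap's deepest point; the per-site target velocity is
  the transient peak speed times the weight, along the inward normal.
  For caps generated from a parametric network, `d` is the analytic
  in-plane distance to the vessel wall and `d_ref` the cap inradius; a
  circular cap then reconstructs the Poiseuille parabola exactly.  (The
  generic fallback measures `d` by nearest-solid search in the cap plane;
  it is noisier on a staircase rim and reproduces the parabola only
  approximately.)
* **Pressure outlets:** all populations of an outlet-plane site are
  replaced by the equilibrium at a fixed reference density (default
  lattice 1.0) and the interior neighbour's velocity.  This pins the
  outlet pressure and makes its normal gradient vanish.  All outlets
  share one reference density; Windkessel-type impedances are out of
  scope.  Corner sites resolve wall links before iolet links.

## Pulsatile waveforms and stroke scenarios

The healthy inlet signal is `v(t) = ramp(t)·v_max·p(φ)` with a
raised-cosine systolic pulse on a diastolic floor `p_min = 0.25`
(peak phase 0.25, half-width 0.3 of a period), period `T = 0.8667 s` so
three beats span 2.6 s, and a linear warm-up ramp (default 0.4 s) easing
the domain from rest.  The shape is configurable and can be replaced by a
sampled two-column trace.  Default peak speeds: basilar 0.4 m/s, carotids
0.5 m/s — order-of-magnitude arterial values; all configurable.

A stroke multiplies the basilar signal by a continuous, piecewise-linear,
non-increasing envelope g(t) with a common onset (default: start of the
second beat after warm-up):

| id | ramp              | residual |
|----|-------------------|----------|
| 1  | T/4               | 0        |
| 2  | to simulation end | 0        |
| 3  | T/4               | 0.50     |
| 4  | T/4               | 0.30     |
| 5  | T/4               | 0.10     |

Scenarios 3–5 reuse scenario 1's quarter-beat ramp.  During scenario 2's
slow decline the stroke inlet can transiently exceed the healthy flow
*downstream* (outlet ratios above one) while never exceeding it at the
inlet itself.

## Synthetic vessel geometry

Networks are unions of capsules (cylinders with hemispherical joins, so
junctions blend smoothly); segment ends may carry axis-aligned planar
caps stamped as inlet/outlet site planes.  A site is fluid iff its center
lies inside the union; radii below 3 dx are refused, fluid connectivity
(19-neighbourhood) is verified, and every domain is padded by solid
layers.

The idealized circle of Willis is planar (ring at one height, carotids
entering vertically), mirror-symmetric, spanning ~25 × 20 mm, with
literature-typical radii: ICA 2.0, BA 1.6, MCA 1.4, PCA 1.2, ACA 1.2,
PCoA 0.7, ACoA 0.7 mm.  Inlets: basilar (BA) and both internal carotids;
outlets: L/R PCA, MCA, ACA; connecting segments: P1, A1, ACoA and the two
removable PCoA.  The anatomical variants remove the left or right PCoA;
the remaining stubs close smoothly (the blocked vessel is simply absent,
equivalent to stagnant fluid behind a smooth wall).

What this generator does *not* emulate: patient-specific curvature,
tapering, non-planar topology and calibre asymmetries of CTA-derived
vessels.  Consequently the package reproduces redistribution *rankings
and directions* (which outlets lose most, how a missing PCoA shifts the
burden) but not patient-specific percentage ratios; the tests assert
exactly that.

## Observables

* **Flow rate:** `Q = dx² Σ u_n` over the plane one site inside each cap,
  positive outward at outlets and inward at inlets.
* **Flow ratio:** pointwise ratio of window-averaged stroke and healthy
  series (default window T/20); samples with a near-zero healthy
  denominator are masked.  Summary statistic: the ratio of the two flows
  cycle-averaged over the final beat, which is robust to diastolic
  zero-crossings.
* **Wall shear stress:** from the non-equilibrium momentum flux
  `sigma = −(1 − 1/(2 tau)) Σ c_i c_i (f_i − f_i^eq)`, with f_eq at the
  site's own moments.  Wall normals come from the central-difference
  gradient of a 3×3×3 box-smoothed solid indicator (robust on staircase
  walls; periodic axes wrap).  The reported value is the tangential
  traction `|σ·n̂ − (n̂·σ·n̂)n̂|`, linearly extrapolated to the wall from
  two interior samples along the normal: the raw wall-adjacent estimate is
  biased several percent low (site depth plus bounce-back pollution of
  the non-equilibrium part), and the extrapolated estimator is exact for
  Couette flow and within ~1 % of the Poiseuille wall stress at 32 sites
  per diameter.  Sites with degenerate normals (isolated voxels) are
  skipped and counted.  Exported maps default to the 0–20 Pa display
  clamp.
* **Velocity magnitude:** |u| per site in m/s plus the domain maximum.

## Numerical choices

* Initial state: equilibrium at lattice density 1; steady benchmarks
  preload the analytic profile so only boundary layers need to relax.
* Steady-state detection: step-to-step velocity change below a relative
  tolerance (1e-7 of the peak) over 200-step blocks.
* Divergence handling: any nonfinite population or nonpositive density
  aborts with the offending site and step; silent NaN propagation is the
  dominant LBM failure mode.
* Mass is conserved exactly (to float rounding) in closed domains;
  the quiescent equilibrium is a global fixed point when inlets are at
  rest and outlets at the initial density.
* Velocity-set invariants (Σw = 1, isotropy, opposite-map involution) are
  checked in exact rational arithmetic in the tests.

## Desk-scale study sizes

The redistribution study in the test suite runs the idealized circle of
Willis at dx = 0.2 mm (~49,000 fluid sites, the coarsest grid resolving
the 0.7 mm communicating arteries at 3 sites per radius), with reduced
peak inlet speeds (BA 0.024, ICA 0.03 m/s, Re ≈ 30) and a shortened
protocol: 0.3 s warm-up, stroke at the end of warm-up, two beats
(dt ≈ 0.27 ms, tau = 0.58, ~7600 steps per run).  In this viscous regime
the flow is quasi-steady within a beat and the outlet split is governed
by the network's resistance topology, so redistribution rankings are
insensitive to the Reynolds reduction — which is what the qualitative
checks assert.  Two artifacts of the regime are documented rather than
hidden: densities vary by a few percent across the network (large viscous
pressure drops at coarse resolution), so velocity-flux inlet/outlet
balance holds only to that compressibility level, while *mass* flux
balances exactly; and percentage ratios differ from patient-geometry
values.

## Known limitations

* BGK only (no TRT/MRT); accuracy at `tau` near 1/2 relies on low grid
  Reynolds numbers.
* Staircase walls with halfway bounce-back: first-order wall placement,
  no curved-boundary interpolation.
* Caps must be axis-aligned planes; oblique iolets are unsupported.
* No Windkessel outlets, non-Newtonian rheology, elastic walls, thermal
  coupling or turbulence modelling.
* Wall shear stress is defined on wall-adjacent voxels (with wall
  extrapolation), not on a reconstructed surface mesh.
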