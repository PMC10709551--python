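# willisflow

Lattice-Boltzmann simulation of cerebral blood flow during basilar-artery
stroke, at desk scale.

The circle of Willis is the ring of arteries at the base of the brain that
joins the basilar and internal carotid supplies and feeds the six cerebral
outflow arteries (left/right posterior, middle and anterior cerebral
arteries).  Its redundant connections can reroute blood when a feeding
vessel is blocked — but the ring is anatomically complete in only a
minority of people.  `willisflow` simulates how flow redistributes in the
seconds during and after a basilar-artery infarct, on idealized parametric
circle-of-Willis geometries with and without the posterior communicating
arteries (PCoA), for users studying cerebral hemodynamics who want a
self-contained, reproducible solver rather than an HPC deployment.

## Model

The solver is a D3Q19 single-relaxation-time (BGK) lattice-Boltzmann
method.  Nineteen populations f_i per lattice site evolve by

    f_i(x + c_i, t + 1) = f_i(x, t) - [f_i(x, t) - f_i^eq(rho, u)] / tau

with the second-order Maxwell–Boltzmann equilibrium and moments
rho = Σ f_i, rho u = Σ c_i f_i, p = c_s² rho (c_s² = 1/3).  This recovers
incompressible Navier–Stokes at low Mach number with kinematic viscosity

    nu = c_s² (tau − 1/2) δx² / δt.

Blood is treated as Newtonian (nu = 4.0×10⁻⁶ m²/s, rho = 1000 kg/m³); on
the reference discretization δx = 25 µm, δt = 1 µs this gives
tau = 0.5192.  Walls are halfway bounce-back (no-slip), velocity inlets
are moving-wall bounce-back driven by pulsatile waveforms with a parabolic
cap weighting (a circular inlet reconstructs Poiseuille flow), and outlets
are fixed-density planes with zeroth-order velocity extrapolation, which
enforces a zero normal pressure gradient.

A stroke is modeled as a transform of the basilar inlet signal: five
scenarios multiply the healthy waveform by a piecewise-linear envelope —
(1) sudden halt within a quarter heartbeat, (2) linear decline to zero by
the end of the run, (3–5) linear restriction to 50/30/10 % of healthy
flow.  Observables are per-outlet volumetric flow rates, stroke-to-healthy
flow ratios, velocity-magnitude fields and wall shear stress from the
non-equilibrium momentum flux.

## Worked example

```python
from willisflow import UnitSystem, relaxation_time
from willisflow.validation import poiseuille_tube

print(relaxation_time(4.0e-6, UnitSystem(dx=25e-6, dt=1e-6)))
# 0.5192

res = poiseuille_tube(r_sites=10)   # tube, 20 sites across the diameter
print(f"profile L2 error {res.profile_l2_error:.4f}, "
      f"flow-rate error {res.flow_rate_error:.4f}, "
      f"WSS error {res.wss_error:.4f}")
# profile L2 error 0.0204, flow-rate error 0.0076, WSS error 0.0300
```

A paired healthy/stroke study on the full circle of Willis (sudden-halt
scenario, dx = 0.2 mm, viscous-regime inlet speeds — see
`docs/methods.md`):

```python
from dataclasses import replace
from willisflow.pipeline import RunConfig, run, compare

base = RunConfig(geometry="cow_full", dx=2e-4,
                 peak_velocity={"BA": 0.024, "LICA": 0.03, "RICA": 0.03},
                 warmup=0.3, duration=0.3 + 2 * (2.6 / 3),
                 stroke_onset=0.3, cadence=5e-3)
healthy = run(base)
stroke = run(replace(base, scenario=1))
table, series = compare(healthy, stroke)
print(table[["outlet", "final_beat_ratio"]].to_string(index=False))
```

```
outlet  final_beat_ratio
  RPCA          0.154226
  LPCA          0.154226
  RACA          0.969498
  LACA          0.969498
  RMCA          0.975122
  LMCA          0.975122
```

`final_beat_ratio` is the stroke/healthy outlet flow averaged over the
last simulated heartbeat.  After a sudden basilar halt the two posterior
cerebral arteries lose by far the most flow (here ~85 %, since they are
then fed only through the narrow communicating arteries), while the middle
and anterior cerebral arteries, supplied by the carotids, retain ~97 % —
the ranking the physiology predicts.  Removing a PCoA deepens the
ipsilateral PCA loss further.

The same studies are scriptable from the shell: `willisflow run`,
`compare`, `matrix` (all variants × scenarios), `converge` and
`validate`.

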