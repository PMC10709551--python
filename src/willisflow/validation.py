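"""Analytic validation drivers: shear-wave decay, Poiseuille tube, Couette.

These set up the classic closed-form flows on small lattices and return
measured-vs-analytic figures.  The test suite asserts their tolerances;
the CLI ``validate`` subcommand prints them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import observables, vessel_geometry as vg
from .lbm_core import CS2, Simulation, UnitSystem, macroscopics


def shear_wave_viscosity(tau, n=32, u0=1e-4, n_periods=2.0):
    """Fit the decay rate of u_y(x, t) = U0 sin(kx) exp(-nu k^2 t) on a
    fully periodic box; returns (nu_fitted, nu_nominal) in lattice units.

    ``n`` sites per wavelength; the fit spans ``n_periods`` e-folding
    times of the nominal decay.
    """
    nu = CS2 * (tau - 0.5)
    dom = vg.periodic_box((n, 4, 4), dx=1.0)
    units = UnitSystem(dx=1.0, dt=1.0)
    k = 2.0 * np.pi / n
    x = dom.comp_coords[:, 0] + 0.5
    u = np.zeros((dom.n_comp, 3))
    u[:, 1] = u0 * np.sin(k * x)
    sim = Simulation(dom, units, tau, initial_velocity=u)

    t_decay = 1.0 / (nu * k ** 2)
    total = int(n_periods * t_decay)
    block = max(total // 40, 1)
    basis = np.sin(k * x)
    norm = (basis ** 2).sum()
    ts, amps = [], []
    for _ in range(40):
        sim.advance(block)
        uy = macroscopics(sim.f).velocity[:, 1]
        amps.append((uy * basis).sum() / norm)
        ts.append(sim.step_count)
    ts = np.asarray(ts, float)
    amps = np.asarray(amps)
    slope = np.polyfit(ts, np.log(amps), 1)[0]
    return -slope / k ** 2, nu


@dataclass
class PoiseuilleResult:
    """Measured-vs-analytic figures for steady tube flow."""

    profile_l2_error: float      # relative L2 vs the parabola, mid-plane
    flow_rate: float             # measured outlet Q, m^3/s
    flow_rate_analytic: float    # pi R^2 u_max / 2
    wss_mean: float              # mean over mid-tube wall sites, Pa
    wss_analytic: float          # 2 rho nu u_max / R
    sim: object
    domain: object
    units: object
    tau: float
    u_peak: float

    @property
    def flow_rate_error(self):
        return abs(self.flow_rate - self.flow_rate_analytic) / \
            self.flow_rate_analytic

    @property
    def wss_error(self):
        return abs(self.wss_mean - self.wss_analytic) / self.wss_analytic


def poiseuille_tube(r_sites=16, tau=0.8, u_lat_peak=0.04, nu=4.0e-6,
                    rho=1000.0, length_radii=3.0, tol=1e-7, max_steps=40000):
    """Drive a voxelized tube with a steady parabolic inlet to steady state.

    Resolution is ``r_sites`` lattice sites per tube radius.  The physical
    scales follow from (nu, tau, r_sites): dx = R/r_sites and dt from the
    viscosity relation; the peak speed is set by the target lattice speed.
    The initial state is preloaded with the analytic profile so the run
    only has to relax the boundary layers.
    """
    R = 1.6e-3
    dx = R / r_sites
    dt = CS2 * (tau - 0.5) * dx ** 2 / nu
    units = UnitSystem(dx=dx, dt=dt, rho_ref=rho)
    u_peak = u_lat_peak * units.velocity
    L = length_radii * R

    net = vg.build_tube(R, L)
    dom = vg.voxelize(net, dx)

    centers = dom.site_centers(dom.comp_coords)
    r2 = centers[:, 0] ** 2 + centers[:, 2] ** 2    # tube axis: x=z=0
    u0 = np.zeros((dom.n_comp, 3))
    u0[:, 1] = u_lat_peak * np.clip(1.0 - r2 / R ** 2, 0.0, None)

    inlet_id = dom.port("in").id
    sim = Simulation(dom, units, tau,
                     inlet_velocity={inlet_id: lambda t: u_peak},
                     initial_velocity=u0)

    prev = u0[:, 1].copy()
    for _ in range(max_steps // 200):
        sim.advance(200)
        uy = macroscopics(sim.f).velocity[:, 1]
        if np.abs(uy - prev).max() < tol * u_lat_peak:
            break
        prev = uy.copy()

    m = macroscopics(sim.f)

    # mid-plane profile vs the analytic parabola
    ymid = dom.shape[1] // 2
    sel = dom.comp_coords[:, 1] == ymid
    u_num = m.velocity[sel, 1] * units.velocity
    u_ana = u_peak * (1.0 - r2[sel] / R ** 2)
    l2 = np.sqrt(((u_num - u_ana) ** 2).sum() / (u_ana ** 2).sum())

    q = observables.outlet_flow_rate(m, dom, "out", units)
    q_ana = np.pi * R ** 2 * u_peak / 2.0

    field = observables.wss_field(sim.f, tau, dom, units)
    band = (np.abs(field.positions[:, 1] - L / 2.0) < L / 4.0)
    wss_mean = float(field.wss[band].mean())
    wss_ana = 2.0 * rho * nu * u_peak / R

    return PoiseuilleResult(
        profile_l2_error=float(l2), flow_rate=q, flow_rate_analytic=q_ana,
        wss_mean=wss_mean, wss_analytic=wss_ana, sim=sim, domain=dom,
        units=units, tau=tau, u_peak=u_peak)


def couette_channel(nz_fluid=20, tau=0.8, u_lat_wall=0.02, nu=4.0e-6,
                    rho=1000.0, n_steps=4000):
    """Planar Couette flow: bottom no-slip wall, top moving wall, periodic
    in the flow and spanwise directions.

    Returns (mean wall shear stress Pa, analytic rho*nu*U/H, sim, domain).
    """
    nx = ny = 4
    nz = nz_fluid + 2
    labels = np.full((nx, ny, nz), vg.FLUID, dtype=np.uint8)
    labels[:, :, 0] = vg.SOLID
    labels[:, :, -1] = vg.INLET
    coords = np.argwhere(labels == vg.INLET)
    H = nz_fluid  # lattice: walls at z=0.5 and z=nz-1.5
    dx = 1.0e-4
    dt = CS2 * (tau - 0.5) * dx ** 2 / nu
    units = UnitSystem(dx=dx, dt=dt, rho_ref=rho)
    dom = vg.VoxelDomain.from_labels(
        labels, dx, periodic=(True, True, False),
        inlet_ports=[("lid", coords, np.array([0, 0, -1]))])
    # tangential moving wall: override the velocity direction of the lid
    dom.inlets[0].direction = np.array([1.0, 0.0, 0.0])

    gamma = u_lat_wall / H
    z = dom.comp_coords[:, 2].astype(float)
    u0 = np.zeros((dom.n_comp, 3))
    u0[:, 0] = gamma * (z - 0.5)
    u_wall = u_lat_wall * units.velocity
    sim = Simulation(dom, units, tau,
                     inlet_velocity={0: lambda t: u_wall},
                     initial_velocity=u0)
    sim.advance(n_steps)

    field = observables.wss_field(sim.f, tau, dom, units)
    wss_mean = float(field.wss.mean())
    gamma_phys = u_wall / (H * dx)
    return wss_mean, rho * nu * gamma_phys, sim, dom


def mass_balance(record):
    """Relative imbalance between total inlet and outlet flow over the
    final sampled beat of a run record."""
    period = record.config.period
    q_in = sum(observables.cycle_average(s, period)
               for s in record.inlet_series.values())
    q_out = sum(observables.cycle_average(s, period)
                for s in record.outlet_series.values())
    return abs(q_in - q_out) / abs(q_in)
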