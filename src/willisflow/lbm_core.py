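"""Single-relaxation-time (BGK) lattice-Boltzmann core on the D3Q19 stencil.

The solver state is the set of 19 mesoscopic populations per lattice site;
macroscopic density, velocity and pressure are moments of those populations.
One time step is collide -> stream -> wall links -> inlet links -> outlets,
and the incompressible Navier-Stokes equations are recovered in the
low-Mach limit with kinematic viscosity

    nu = c_s^2 (tau - 1/2) dx^2 / dt,   c_s^2 = 1/3.

All populations are stored direction-major with shape ``(19, n_sites)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import InvalidParameterError, SimulationDivergedError

CS2 = 1.0 / 3.0  #: lattice speed of sound squared


def _build_d3q19():
    dirs = [(0, 0, 0)]
    # face neighbours
    for a in range(3):
        for s in (1, -1):
            v = [0, 0, 0]
            v[a] = s
            dirs.append(tuple(v))
    # edge neighbours
    for a in range(3):
        for b in range(a + 1, 3):
            for sa in (1, -1):
                for sb in (1, -1):
                    v = [0, 0, 0]
                    v[a], v[b] = sa, sb
                    dirs.append(tuple(v))
    c = np.array(dirs, dtype=np.int64)
    w = np.empty(19)
    for i, d in enumerate(dirs):
        n = sum(abs(x) for x in d)
        w[i] = (Fraction(1, 3), Fraction(1, 18), Fraction(1, 36))[n]
    opp = np.array([dirs.index(tuple(-x for x in d)) for d in dirs],
                   dtype=np.int64)
    return c, w, opp


@dataclass(frozen=True)
class VelocitySet:
    """A discrete velocity stencil: directions, weights and opposites."""

    directions: np.ndarray   # (q, 3) int
    weights: np.ndarray      # (q,) float
    opposite: np.ndarray     # (q,) int, involution
    speed_of_sound_sq: float = CS2

    @property
    def q(self):
        return len(self.weights)

    def weights_exact(self):
        """Weights as exact rationals (for moment-identity checks)."""
        table = {0: Fraction(1, 3), 1: Fraction(1, 18), 2: Fraction(1, 36)}
        return [table[int(np.abs(d).sum())] for d in self.directions]


_C, _W, _OPP = _build_d3q19()
D3Q19 = VelocitySet(directions=_C, weights=_W, opposite=_OPP)


@dataclass(frozen=True)
class UnitSystem:
    """Physical <-> lattice scaling defined by dx (m), dt (s), rho_ref (kg/m^3)."""

    dx: float
    dt: float
    rho_ref: float = 1000.0

    def __post_init__(self):
        if self.dx <= 0 or self.dt <= 0 or self.rho_ref <= 0:
            raise InvalidParameterError(
                "dx, dt and rho_ref must all be positive")

    @property
    def velocity(self):
        """m/s per lattice velocity unit."""
        return self.dx / self.dt

    @property
    def pressure(self):
        """Pa per lattice pressure/stress unit."""
        return self.rho_ref * self.dx ** 2 / self.dt ** 2

    @property
    def flow_rate(self):
        """m^3/s per lattice flow-rate unit."""
        return self.dx ** 3 / self.dt

    def velocity_to_lattice(self, v):
        return np.asarray(v) / self.velocity

    def velocity_to_physical(self, v):
        return np.asarray(v) * self.velocity


def relaxation_time(nu_phys, units):
    """BGK relaxation time tau = nu*dt/(c_s^2 dx^2) + 1/2.

    Parameters
    ----------
    nu_phys : float
        Kinematic viscosity in m^2/s (blood: ~4.0e-6).
    units : UnitSystem
    """
    if nu_phys <= 0:
        raise InvalidParameterError("kinematic viscosity must be positive")
    tau = nu_phys * units.dt / (CS2 * units.dx ** 2) + 0.5
    if tau <= 0.5:
        raise InvalidParameterError(f"derived tau = {tau} <= 1/2")
    return tau


def viscosity_from_tau(tau, units):
    """Inverse of :func:`relaxation_time`: nu = c_s^2 (tau-1/2) dx^2/dt."""
    if tau <= 0.5:
        raise InvalidParameterError("tau must exceed 1/2")
    return CS2 * (tau - 0.5) * units.dx ** 2 / units.dt


def equilibrium(rho, u, vset=D3Q19):
    """Second-order Maxwell-Boltzmann equilibrium populations.

    ``rho`` has shape () or (n,), ``u`` shape (3,) or (n, 3); the result has
    shape (19,) or (19, n).  Sum of the result is exactly rho and its first
    moment exactly rho*u (to rounding).
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    scalar = u.ndim == 1
    if scalar:
        u = u[None, :]
        rho = np.atleast_1d(rho)
    if np.any(rho <= 0):
        raise InvalidParameterError("equilibrium requires rho > 0")
    cu = vset.directions.astype(float) @ u.T          # (19, n)
    usq = np.einsum("na,na->n", u, u)                 # (n,)
    f = vset.weights[:, None] * rho[None, :] * (
        1.0 + 3.0 * cu + 4.5 * cu ** 2 - 1.5 * usq[None, :])
    return f[:, 0] if scalar else f


@dataclass
class MacroscopicField:
    """Zeroth/first moments of a distribution field (lattice units)."""

    density: np.ndarray    # (n,)
    velocity: np.ndarray   # (n, 3)

    @property
    def pressure(self):
        return CS2 * self.density


def macroscopics(f, vset=D3Q19, check=True):
    """Density, velocity and pressure moments of populations ``f`` (19, n)."""
    f = np.asarray(f, dtype=float)
    scalar = f.ndim == 1
    f2 = f[:, None] if scalar else f
    rho = f2.sum(axis=0)
    if check and np.any(rho <= 0):
        s = int(np.argmax(rho <= 0))
        raise SimulationDivergedError(
            f"nonpositive density at site {s}", site=s)
    mom = vset.directions.astype(float).T @ f2        # (3, n)
    u = (mom / rho).T
    return MacroscopicField(density=rho, velocity=u)


def collide_bgk(f, tau, vset=D3Q19):
    """BGK collision f <- f - (f - f_eq)/tau; conserves mass and momentum."""
    if tau <= 0.5:
        raise InvalidParameterError("tau must exceed 1/2")
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        i, s = np.argwhere(~np.isfinite(f))[0]
        raise SimulationDivergedError(
            f"nonfinite population (direction {i}, site {s})", site=int(s))
    m = macroscopics(f, vset)
    feq = equilibrium(m.density, m.velocity, vset)
    return f + (feq - f) / tau


def stream(f_post, domain, vset=D3Q19):
    """Pull-streaming over fluid-fluid links of ``domain``.

    ``f_post`` are post-collision populations on the domain's computational
    sites.  Links whose upstream neighbour is a wall or an inlet are left
    holding the same-site post-collision value; the boundary_conditions
    module overwrites them.  Fully periodic domains have no such links.
    """
    pull = domain.pull
    f_new = f_post.copy()
    for i in range(vset.q):
        src = pull[i]
        ok = src >= 0
        f_new[i, ok] = f_post[i, src[ok]]
    return f_new


@dataclass(frozen=True)
class StabilityReport:
    """Low-Mach diagnostic for a planned run."""

    lattice_speed: float
    mach: float
    tau: float
    mach_cap: float
    passed: bool

    def __str__(self):
        status = "PASS" if self.passed else "FAIL"
        return (f"[{status}] u_lat = {self.lattice_speed:.4g}, "
                f"Ma = {self.mach:.4g} (cap {self.mach_cap}), "
                f"tau = {self.tau:.4g}")


def stability_report(u_max_phys, units, tau, mach_cap=0.1):
    """Check that the peak flow speed keeps the lattice Mach number low.

    The LBM recovers Navier-Stokes only when Ma = u_lat/c_s is small; error
    terms scale with Ma^2.  Supersonic lattice speeds always fail.
    """
    if u_max_phys < 0:
        raise InvalidParameterError("speed must be nonnegative")
    u_lat = u_max_phys * units.dt / units.dx
    mach = u_lat / np.sqrt(CS2)
    passed = bool(mach <= mach_cap and tau > 0.5 and mach < 1.0)
    return StabilityReport(lattice_speed=u_lat, mach=mach, tau=tau,
                           mach_cap=mach_cap, passed=passed)


@dataclass
class DistributionField:
    """The 19 populations per computational site of a voxel domain."""

    f: np.ndarray            # (19, n_sites)
    domain: object = None

    def macroscopics(self):
        return macroscopics(self.f)

    @property
    def mass(self):
        return float(self.f.sum())


@dataclass
class DiagnosticsLog:
    """Per-sample solver health record appended during a run."""

    rows: list = field(default_factory=list)

    def append(self, step, t, mass, max_u_lat):
        self.rows.append(
            {"step": step, "time_s": t, "mass": mass, "max_u_lat": max_u_lat})

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.rows)


class Simulation:
    """Time integrator binding a voxel domain, units and boundary drivers.

    Parameters
    ----------
    domain : VoxelDomain
        Classified, link-compiled lattice (see vessel_geometry).
    units : UnitSystem
    tau : float
        BGK relaxation time (> 1/2).
    inlet_velocity : mapping iolet-id -> callable t_s -> peak speed m/s
        Transient peak speed for each velocity inlet; per-site targets are
        the peak scaled by the domain's parabolic inlet weights.
    outlet_density : float or mapping iolet-id -> float
        Fixed lattice outlet density (reference pressure), default 1.0.
    """

    def __init__(self, domain, units, tau, inlet_velocity=None,
                 outlet_density=1.0, initial_density=1.0,
                 initial_velocity=None, check_interval=200):
        if tau <= 0.5:
            raise InvalidParameterError("tau must exceed 1/2")
        self.domain = domain
        self.units = units
        self.tau = tau
        self.vset = D3Q19
        self.check_interval = int(check_interval)
        self.step_count = 0
        self.log = DiagnosticsLog()

        inlet_velocity = inlet_velocity or {}
        self._inlet_drivers = []
        for port in domain.inlets:
            drv = inlet_velocity.get(port.id)
            if drv is None:
                drv = lambda t: 0.0
            self._inlet_drivers.append(drv)

        n_out = len(domain.outlet_sites)
        if np.isscalar(outlet_density):
            self._rho_out = np.full(n_out, float(outlet_density))
        else:
            self._rho_out = np.empty(n_out)
            for port in domain.outlets:
                self._rho_out[domain.outlet_slice(port.id)] = \
                    outlet_density[port.id]

        n = domain.n_comp
        u0 = np.zeros((n, 3)) if initial_velocity is None else initial_velocity
        self.f = equilibrium(np.full(n, float(initial_density)), u0)
        self._f_new = np.empty_like(self.f)
        self._rho_buf = np.empty(n)

    @property
    def time(self):
        """Physical time in seconds."""
        return self.step_count * self.units.dt

    def _inlet_ub(self, t):
        """Per-inlet-site lattice velocity targets at time t (m, 3)."""
        dom = self.domain
        ub = np.zeros((len(dom.inlet_weights), 3))
        for port, drv in zip(dom.inlets, self._inlet_drivers):
            sl = dom.inlet_slice(port.id)
            v_lat = float(drv(t)) * self.units.dt / self.units.dx
            ub[sl] = v_lat * dom.inlet_weights[sl, None] * \
                port.direction[None, :]
        return ub

    def advance(self, n_steps):
        """Advance ``n_steps`` time steps (collide, stream, boundaries)."""
        from . import _kernels
        dom = self.domain
        for _ in range(int(n_steps)):
            ub = self._inlet_ub(self.time)
            _kernels.fused_step(
                self.f, self._f_new, self._rho_buf,
                dom.pull, dom.link_inlet_site,
                self.vset.directions, self.vset.weights, self.vset.opposite,
                1.0 / self.tau, ub,
                dom.outlet_sites, dom.outlet_interior, self._rho_out)
            self.f, self._f_new = self._f_new, self.f
            self.step_count += 1
            if self.step_count % self.check_interval == 0:
                self._health_check()

    def _health_check(self):
        if not np.all(np.isfinite(self.f)):
            i, s = np.argwhere(~np.isfinite(self.f))[0]
            raise SimulationDivergedError(
                f"nonfinite population at comp site {s} "
                f"(grid {tuple(self.domain.comp_coords[s])}), "
                f"step {self.step_count}",
                site=tuple(self.domain.comp_coords[s]), step=self.step_count)
        rho = self.f.sum(axis=0)
        if np.any(rho <= 0):
            s = int(np.argmax(rho <= 0))
            raise SimulationDivergedError(
                f"nonpositive density at comp site {s} "
                f"(grid {tuple(self.domain.comp_coords[s])}), "
                f"step {self.step_count}",
                site=tuple(self.domain.comp_coords[s]), step=self.step_count)

    def sample(self):
        """Log mass and peak lattice speed at the current step."""
        m = macroscopics(self.f)
        umax = float(np.sqrt((m.velocity ** 2).sum(axis=1)).max())
        self.log.append(self.step_count, self.time, float(self.f.sum()), umax)
        return m

    def macroscopic(self):
        return macroscopics(self.f)

    def run_until(self, t_end, callback=None, cadence_steps=100):
        """Advance to physical time ``t_end``, invoking ``callback(sim)``
        every ``cadence_steps`` steps (and at the end)."""
        while self.time < t_end - 0.5 * self.units.dt:
            remaining = int(round((t_end - self.time) / self.units.dt))
            block = min(cadence_steps, remaining)
            self.advance(block)
            if callback is not None:
                callback(self)


def step_reference(sim_f, domain, tau, inlet_ub, rho_out, vset=D3Q19):
    """One time step via the separate numpy operations (oracle path).

    Composes collide_bgk, stream and the boundary_conditions resolvers in
    the documented order.  Used to cross-check the fused kernel; not meant
    for production time stepping.
    """
    from . import boundary_conditions as bc
    f_post = collide_bgk(sim_f, tau, vset)
    rho = sim_f.sum(axis=0)
    f_new = stream(f_post, domain, vset)
    f_new = bc.apply_walls(f_new, f_post, domain, vset)
    f_new = bc.apply_velocity_inlet(f_new, f_post, domain, inlet_ub, rho,
                                    vset)
    f_new = bc.apply_pressure_outlet(f_new, domain, rho_out, vset)
    return f_new
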