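"""Wall, velocity-inlet and pressure-outlet link resolution.

These are the reference (numpy) implementations of the boundary update,
applied after streaming in the order walls -> inlets -> outlets:

* walls: halfway bounce-back, no-slip at a wall plane half a lattice
  spacing beyond the last fluid site;
* velocity inlets: moving-wall (momentum-corrected) bounce-back imposing a
  per-site target velocity, the peak inlet speed scaled by the parabolic
  cap weights;
* pressure outlets: all populations of an outlet-plane site replaced by the
  equilibrium at the fixed outlet density and the interior neighbour's
  velocity (zeroth-order extrapolation), which pins the outlet pressure and
  makes its normal gradient vanish.

The production time stepper fuses the same updates into one compiled
kernel (_kernels.fused_step); the test suite checks the two paths agree to
rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .lbm_core import CS2, D3Q19, equilibrium


@dataclass(frozen=True)
class IoletSpec:
    """Runtime boundary assignment for one iolet plane."""

    name: str
    kind: str                    # "velocity_inlet" | "pressure_outlet"
    waveform: object = None      # callable t_s -> peak speed m/s (inlets)
    reference_density: float = 1.0   # lattice rho_out (outlets)

    def __post_init__(self):
        if self.kind not in ("velocity_inlet", "pressure_outlet"):
            raise InvalidParameterError(f"unknown iolet kind {self.kind!r}")


def apply_walls(f_new, f_post, domain, vset=D3Q19):
    """Halfway bounce-back on all fluid->SOLID links (pull code -1)."""
    out = f_new.copy()
    for i in range(vset.q):
        j = vset.opposite[i]
        sel = domain.pull[i] == -1
        out[i, sel] = f_post[j, sel]
    return out


def apply_velocity_inlet(f_new, f_post, domain, inlet_ub, rho_site,
                         vset=D3Q19):
    """Moving-wall bounce-back on fluid->INLET links (pull code -2).

    ``inlet_ub`` is the per-inlet-site lattice target velocity (m, 3);
    ``rho_site`` the pre-collision density of each computational site.
    For each link crossing the cap the reflected population receives a
    momentum correction  -2 w_i rho0 (c_i . u_b)/c_s^2  so that, after
    transients, the realized normal velocity matches the target.  A zero
    target reduces exactly to the static wall update.
    """
    if np.any(np.linalg.norm(inlet_ub, axis=-1) >= np.sqrt(CS2)):
        raise InvalidParameterError(
            "inlet target speed reaches the lattice sound speed")
    out = f_new.copy()
    for i in range(vset.q):
        j = vset.opposite[i]
        sel = domain.pull[i] == -2
        if not np.any(sel):
            continue
        m = domain.link_inlet_site[i, sel]
        cu = inlet_ub[m] @ vset.directions[j].astype(float)
        out[i, sel] = f_post[j, sel] - 2.0 * vset.weights[j] / CS2 * \
            rho_site[sel] * cu
    return out


def apply_pressure_outlet(f_new, domain, rho_out, vset=D3Q19):
    """Fixed-density outlet planes with zeroth-order velocity extrapolation.

    ``rho_out`` is a scalar or per-outlet-site array of lattice densities.
    """
    out = f_new.copy()
    if len(domain.outlet_sites) == 0:
        return out
    rho_out = np.broadcast_to(np.asarray(rho_out, float),
                              domain.outlet_sites.shape)
    fn = f_new[:, domain.outlet_interior]
    rho_n = fn.sum(axis=0)
    u_n = (vset.directions.astype(float).T @ fn / rho_n).T
    out[:, domain.outlet_sites] = equilibrium(rho_out, u_n, vset)
    return out
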