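"""Reported quantities: outlet flow rates, stroke-to-healthy ratios, wall
shear stress and velocity-magnitude fields.

Flow rates are plane sums of the normal velocity one site inside each cap.
Wall shear stress is estimated on wall-adjacent fluid sites from the
non-equilibrium momentum flux,

    sigma_ab = -(1 - 1/(2 tau)) sum_i c_ia c_ib (f_i - f_i^eq),

projected onto the local wall tangent plane; wall normals come from the
gradient of a box-smoothed solid-indicator field, which is robust on
staircase walls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .lbm_core import D3Q19, equilibrium, macroscopics
from .vessel_geometry import SOLID

#: Display clamp (Pa) for exported wall-shear-stress maps.
WSS_DISPLAY_RANGE = (0.0, 20.0)


@dataclass
class OutletSeries:
    """Volumetric flow-rate time series at one iolet (SI units)."""

    outlet_id: str
    times: np.ndarray       # s, strictly increasing, constant cadence
    flow: np.ndarray        # m^3/s, positive for outflow

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.flow = np.asarray(self.flow, float)
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("time stamps must increase strictly")

    @property
    def cadence(self):
        return float(self.times[1] - self.times[0])


def plane_flow_rate(velocity, measure_comp, direction, units):
    """Q = dx^2 * sum of normal velocity over a measurement plane (m^3/s).

    ``velocity`` is the lattice velocity field (n_comp, 3); the plane is a
    set of computational sites with a common unit normal; positive sign
    means flow along ``direction``.
    """
    u_n = velocity[measure_comp] @ np.asarray(direction, float)
    return float(u_n.sum()) * units.dx ** 2 * units.velocity


def outlet_flow_rate(state, domain, port_name, units):
    """Flow rate through a named iolet, positive for outflow.

    ``state`` is a populations array (19, n_comp) or a MacroscopicField.
    Measured one site inside the cap plane along the port normal (for
    inlets the sign convention is positive *into* the domain).
    """
    m = state if hasattr(state, "velocity") else macroscopics(state)
    port = domain.port(port_name)
    return plane_flow_rate(m.velocity, port.measure_comp, port.direction,
                           units)


@dataclass
class RatioSeries:
    """Pointwise stroke-to-healthy flow ratio with masked samples where the
    healthy denominator is too close to zero."""

    outlet_id: str
    times: np.ndarray
    ratio: np.ndarray
    masked: np.ndarray      # True where the denominator was unreliable


def _moving_average(x, n):
    if n <= 1:
        return np.asarray(x, float)
    kernel = np.ones(n) / n
    pad = n // 2
    xp = np.pad(np.asarray(x, float), pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad:pad + len(x)]


def flow_ratio(stroke, healthy, smoothing_window=None, rel_floor=0.05):
    """Ratio of window-averaged stroke to healthy flow at one outlet.

    Samples where the smoothed healthy flow falls below ``rel_floor`` times
    its peak magnitude are masked (near-zero denominator).  The two series
    must share their time stamps.
    """
    if len(stroke.times) != len(healthy.times) or \
            not np.allclose(stroke.times, healthy.times):
        raise InvalidParameterError("series time stamps differ")
    if smoothing_window:
        n = max(int(round(smoothing_window / healthy.cadence)), 1)
    else:
        n = 1
    qs = _moving_average(stroke.flow, n)
    qh = _moving_average(healthy.flow, n)
    floor = rel_floor * np.abs(qh).max()
    masked = np.abs(qh) < floor
    ratio = np.where(masked, np.nan, qs / np.where(masked, 1.0, qh))
    return RatioSeries(outlet_id=stroke.outlet_id, times=stroke.times,
                       ratio=ratio, masked=masked)


def cycle_average(series, period, t_start=None, t_end=None):
    """Time-mean of a series over one period (trapezoidal quadrature).

    With ``t_end`` given, averages the final full cycle ending there;
    with ``t_start``, the cycle beginning there.
    """
    times = series.times
    values = series.flow if hasattr(series, "flow") else series.ratio
    if t_end is not None:
        t_start = t_end - period
    elif t_start is not None:
        t_end = t_start + period
    else:
        t_end = times[-1]
        t_start = t_end - period
    tol = 0.5 * (times[1] - times[0]) if len(times) > 1 else 0.0
    if t_start < times[0] - tol or t_end > times[-1] + tol:
        raise InvalidParameterError(
            f"series does not span the requested cycle "
            f"[{t_start:.4g}, {t_end:.4g}] s")
    sel = (times >= t_start - tol) & (times <= t_end + tol)
    t = times[sel]
    v = values[sel]
    return float(np.trapezoid(v, t) / (t[-1] - t[0]))


def final_beat_ratio(stroke, healthy, period, smoothing_window=None):
    """Cycle-averaged stroke/healthy flow over the last full beat.

    Averages the two flows separately over the final beat and takes their
    quotient, which is robust when the instantaneous healthy flow crosses
    zero during diastole.
    """
    qs = cycle_average(stroke, period)
    qh = cycle_average(healthy, period)
    if qh == 0:
        raise InvalidParameterError("healthy cycle-average flow is zero")
    return qs / qh


# --------------------------------------------------------------------------
# field observables
# --------------------------------------------------------------------------

@dataclass
class WallStressField:
    """Shear-stress magnitude (Pa) on wall-adjacent fluid surface sites."""

    positions: np.ndarray   # (n, 3) m
    normals: np.ndarray     # (n, 3) outward unit estimates
    wss: np.ndarray         # (n,) Pa, >= 0
    comp_index: np.ndarray  # (n,) computational-site indices
    skipped: int = 0        # sites dropped for degenerate normals

    def clamped(self, lo=WSS_DISPLAY_RANGE[0], hi=WSS_DISPLAY_RANGE[1]):
        return np.clip(self.wss, lo, hi)


def wall_normals(domain, sigma_smooth=1):
    """Outward wall-normal estimates at all computational sites.

    A 3x3x3 box filter smooths the solid indicator (solid outside the grid)
    and the central-difference gradient of the result points into the wall.
    Returns (normals (n_comp, 3), valid mask); invalid where the gradient
    magnitude is degenerate (isolated voxels).
    """
    solid = (domain.labels == SOLID).astype(float)
    modes = ["wrap" if p else "constant" for p in domain.periodic]
    for _ in range(sigma_smooth):
        solid = ndimage.uniform_filter(solid, size=3, mode=modes, cval=1.0)
    # roll-based central differences: exact on periodic axes; grid-boundary
    # sites are solid padding and never consumed on the others
    grads = [(np.roll(solid, -1, a) - np.roll(solid, 1, a)) /
             (2.0 * domain.dx) for a in range(3)]
    g = np.stack([gr[tuple(domain.comp_coords.T)] for gr in grads], axis=1)
    norm = np.linalg.norm(g, axis=1)
    valid = norm > 1e-6 / domain.dx
    n = np.zeros_like(g)
    n[valid] = g[valid] / norm[valid, None]
    return n, valid


def deviatoric_stress(f, tau, units, vset=D3Q19):
    """Viscous stress tensor (n_comp, 3, 3) in Pa from the non-equilibrium
    populations."""
    if tau <= 0.5:
        raise InvalidParameterError("tau must exceed 1/2")
    m = macroscopics(f, vset)
    fneq = f - equilibrium(m.density, m.velocity, vset)
    c = vset.directions.astype(float)
    cc = np.einsum("ia,ib->iab", c, c)                  # (19, 3, 3)
    pi_neq = np.einsum("iab,in->nab", cc, fneq)
    return -(1.0 - 1.0 / (2.0 * tau)) * pi_neq * units.pressure


def _tangential_traction(sigma, n):
    t = np.einsum("nab,nb->na", sigma, n)
    t_tan = t - (np.einsum("na,na->n", t, n))[:, None] * n
    return np.linalg.norm(t_tan, axis=1)


def wss_field(f, tau, domain, units, wall_extrapolate=True,
              wall_offset=0.5):
    """Wall shear stress on every fluid site with a solid neighbour.

    Traction t = sigma . n_hat; the reported magnitude is the tangential
    component |t - (t . n_hat) n_hat| in Pa.  By default the value is
    linearly extrapolated to the wall from two interior samples along the
    inward normal: the non-equilibrium stress is second-order accurate in
    the bulk but polluted by bounce-back at wall-adjacent sites, and the
    site center sits ~``wall_offset`` dx inside the wall, so the raw
    site value underestimates the wall stress at first order.  Pass
    ``wall_extrapolate=False`` for the raw site estimate.
    """
    sigma = deviatoric_stress(f, tau, units)
    normals, valid = wall_normals(domain)
    idx = domain.wall_adjacent_comp()
    ok = valid[idx]
    skipped = int((~ok).sum())
    idx = idx[ok]
    n = normals[idx]
    wss = _tangential_traction(sigma[idx], n)

    if wall_extrapolate and len(idx):
        coords = domain.comp_coords[idx]
        step = -np.rint(n).astype(np.int64)
        step = np.clip(step, -1, 1)
        shape = np.array(domain.shape)
        c1 = np.clip(coords + step, 0, shape - 1)
        c2 = np.clip(coords + 2 * step, 0, shape - 1)
        j1 = domain.comp_index[tuple(c1.T)]
        j2 = domain.comp_index[tuple(c2.T)]
        good = (j1 >= 0) & (j2 >= 0) & (np.abs(step).sum(axis=1) > 0)
        if np.any(good):
            g = np.nonzero(good)[0]
            n_g = n[g]
            t1 = _tangential_traction(sigma[j1[g]], n_g)
            t2 = _tangential_traction(sigma[j2[g]], n_g)
            pos0 = domain.site_centers(coords[g])
            pos1 = domain.site_centers(c1[g])
            pos2 = domain.site_centers(c2[g])
            h0 = wall_offset * domain.dx
            d1 = h0 + np.einsum("na,na->n", pos0 - pos1, n_g)
            d2 = h0 + np.einsum("na,na->n", pos0 - pos2, n_g)
            sane = d2 > d1
            ext = t1 + (t1 - t2) * d1 / np.where(sane, d2 - d1, 1.0)
            wss[g[sane]] = np.clip(ext[sane], 0.0, None)

    return WallStressField(
        positions=domain.site_centers(domain.comp_coords[idx]),
        normals=n, wss=wss, comp_index=idx, skipped=skipped)


@dataclass
class VelocityMagnitudeField:
    positions: np.ndarray   # (n, 3) m
    magnitude: np.ndarray   # (n,) m/s

    @property
    def max(self):
        return float(self.magnitude.max())


def velocity_magnitude(state, domain, units):
    """Per-site |u| in m/s plus the domain maximum."""
    m = state if hasattr(state, "velocity") else macroscopics(state)
    mag = np.linalg.norm(m.velocity, axis=1) * units.velocity
    return VelocityMagnitudeField(
        positions=domain.site_centers(domain.comp_coords), magnitude=mag)
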