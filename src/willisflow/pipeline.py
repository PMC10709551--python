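"""Config-driven orchestration: paired healthy/stroke runs, comparisons,
the five-scenario experiment matrix and desk-scale convergence studies.

A run is deterministic: geometry is voxelized, the BGK relaxation time is
derived from the fluid viscosity and the discretization, inlets are driven
by the pulsatile waveforms (with an optional stroke envelope on the
basilar inlet), and per-outlet flow-rate series plus optional field
snapshots are recorded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import observables, vessel_geometry as vg, waveforms as wf
from .errors import ConfigError
from .lbm_core import (Simulation, UnitSystem, relaxation_time,
                       stability_report)

#: Default peak inlet speeds (m/s) for the circle-of-Willis inlets.
DEFAULT_PEAK_VELOCITY = {"BA": 0.4, "LICA": 0.5, "RICA": 0.5}


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation.

    ``geometry`` is one of "tube", "bifurcation", "cow_full",
    "cow_no_pcoa_left", "cow_no_pcoa_right", or a path to a saved voxel
    mask.  ``dt`` may be given directly; otherwise it is derived from
    ``target_lattice_speed`` (peak inlet speed mapped to that lattice
    speed, keeping the Mach number low).  When dx changes, rescale dt
    diffusively (dt ~ dx^2) at fixed viscosity to preserve tau.
    """

    geometry: str = "cow_full"
    dx: float = 2.0e-4
    dt: float = None
    target_lattice_speed: float = 0.04
    nu: float = 4.0e-6              # m^2/s, blood kinematic viscosity
    rho: float = 1000.0             # kg/m^3
    peak_velocity: dict = field(
        default_factory=lambda: dict(DEFAULT_PEAK_VELOCITY))
    period: float = wf.DEFAULT_PERIOD
    warmup: float = wf.DEFAULT_WARMUP
    waveform_shape: dict = field(default_factory=dict)  # Waveform extras
    duration: float = None          # s; default warmup + 3 beats
    scenario: int = None            # stroke scenario id (1-5) or None
    stroke_inlet: str = "BA"
    stroke_onset: float = None      # s; default warmup + one period
    cadence: float = 1.0e-3         # s between flow samples
    snapshot_times: tuple = ()      # s; e.g. (1.0, 1.5)
    mach_cap: float = 0.1
    geometry_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.duration is None:
            self.duration = self.warmup + 3.0 * self.period
        if self.duration < self.warmup + self.period:
            raise ConfigError("duration must cover warm-up plus one beat")

    # -- derived quantities ------------------------------------------------

    def resolved_dt(self):
        if self.dt is not None:
            return self.dt
        v_ref = max(self.peak_velocity.values())
        if v_ref <= 0:
            raise ConfigError("peak velocities must be positive")
        return self.target_lattice_speed * self.dx / v_ref

    def units(self):
        return UnitSystem(dx=self.dx, dt=self.resolved_dt(),
                          rho_ref=self.rho)

    def tau(self):
        return relaxation_time(self.nu, self.units())

    def n_steps(self):
        return int(round(self.duration / self.resolved_dt()))

    def to_dict(self):
        d = asdict(self)
        d["geometry_kwargs"] = {k: str(v)
                                for k, v in d["geometry_kwargs"].items()}
        return d

    def config_hash(self):
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True,
                       default=str).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path):
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path):
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


def build_network(config):
    g = config.geometry
    kw = config.geometry_kwargs
    if g == "tube":
        return vg.build_tube(kw.get("radius", 1.6e-3),
                             kw.get("length", 8.0e-3))
    if g == "bifurcation":
        return vg.build_symmetric_bifurcation(
            kw.get("parent_radius", 1.6e-3),
            kw.get("daughter_radius", 1.2e-3),
            kw.get("angle", np.pi / 4))
    if g == "cow_full":
        return vg.build_idealized_cow(vg.CoWVariant.FULL, **kw)
    if g == "cow_no_pcoa_left":
        return vg.build_idealized_cow(vg.CoWVariant.NO_PCOA_LEFT, **kw)
    if g == "cow_no_pcoa_right":
        return vg.build_idealized_cow(vg.CoWVariant.NO_PCOA_RIGHT, **kw)
    raise ConfigError(f"unknown geometry {g!r}")


def build_domain(config):
    p = Path(str(config.geometry))
    if p.suffix == ".npz" and p.exists():
        dom = vg.VoxelDomain.load_mask(p)
        vg.ensure_inlet_weights(dom)
        return dom
    return vg.voxelize(build_network(config), config.dx)


def build_waveforms(config):
    """Per-inlet transient drivers, with the stroke envelope applied to the
    configured stroke inlet when a scenario is set."""
    drivers = {}
    for name, v in config.peak_velocity.items():
        drivers[name] = wf.Waveform(v_max=v, period=config.period,
                                    warmup=config.warmup,
                                    **config.waveform_shape)
    if config.scenario is not None:
        onset = config.stroke_onset
        if onset is None:
            onset = config.warmup + config.period
        table = {s.id: s for s in wf.scenario_defaults(
            period=config.period, onset=onset, warmup=config.warmup)}
        try:
            scen = table[config.scenario]
        except KeyError:
            raise ConfigError(f"unknown scenario id {config.scenario}")
        if config.stroke_inlet not in drivers:
            raise ConfigError(
                f"stroke inlet {config.stroke_inlet!r} has no waveform")
        drivers[config.stroke_inlet] = wf.apply_scenario(
            drivers[config.stroke_inlet], scen, t_end=config.duration)
    return drivers


@dataclass
class Snapshot:
    time: float
    velocity: observables.VelocityMagnitudeField
    wss: observables.WallStressField

    def save(self, path):
        np.savez_compressed(
            path, time=self.time,
            velocity_positions=self.velocity.positions,
            velocity_magnitude=self.velocity.magnitude,
            wss_positions=self.wss.positions,
            wss=self.wss.wss, wss_clamped=self.wss.clamped())


@dataclass
class RunRecord:
    """Everything a run produced: series, snapshots, diagnostics."""

    config: RunConfig
    tau: float
    outlet_series: dict           # name -> OutletSeries
    inlet_series: dict            # name -> OutletSeries (positive inflow)
    snapshots: list
    diagnostics: object           # DataFrame
    fluid_sites: int

    def save(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        import pandas as pd
        rows = []
        for name, s in {**self.inlet_series, **self.outlet_series}.items():
            for t, q in zip(s.times, s.flow):
                rows.append({"time_s": t, "outlet_id": name,
                             "Q_m3_per_s": q})
        pd.DataFrame(rows).to_csv(outdir / "flow_series.csv", index=False)
        self.diagnostics.to_csv(outdir / "diagnostics.csv", index=False)
        with open(outdir / "config.json", "w") as fh:
            json.dump({"config": self.config.to_dict(), "tau": self.tau,
                       "fluid_sites": self.fluid_sites,
                       "config_hash": self.config.config_hash()}, fh,
                      indent=2)
        for snap in self.snapshots:
            snap.save(outdir / f"snapshot_t{snap.time:.3f}s.npz")
        return outdir


def run(config, domain=None, progress=False):
    """Execute one simulation and collect its observables."""
    units = config.units()
    tau = config.tau()
    if domain is None:
        domain = build_domain(config)
    drivers = build_waveforms(config)

    v_ref = max(config.peak_velocity.values())
    rep = stability_report(v_ref, units, tau, mach_cap=config.mach_cap)
    if rep.lattice_speed >= np.sqrt(1.0 / 3.0):
        raise ConfigError(f"supersonic inlet speed: {rep}")

    inlet_velocity = {}
    for port in domain.inlets:
        if port.name not in drivers:
            raise ConfigError(f"no waveform for inlet {port.name!r}")
        inlet_velocity[port.id] = drivers[port.name]

    sim = Simulation(domain, units, tau, inlet_velocity=inlet_velocity)
    cadence_steps = max(int(round(config.cadence / units.dt)), 1)
    n_steps = config.n_steps()

    times = []
    out_flows = {p.name: [] for p in domain.outlets}
    in_flows = {p.name: [] for p in domain.inlets}
    snap_steps = sorted({int(round(t / units.dt))
                         for t in config.snapshot_times})
    snapshots = []

    step = 0
    iterator = range(0, n_steps, cadence_steps)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc=config.geometry)
    for start in iterator:
        block = min(cadence_steps, n_steps - start)
        for target in [s for s in snap_steps
                       if start < s <= start + block]:
            sim.advance(target - step)
            step = target
            m = sim.macroscopic()
            snapshots.append(Snapshot(
                time=sim.time,
                velocity=observables.velocity_magnitude(m, domain, units),
                wss=observables.wss_field(sim.f, tau, domain, units)))
        sim.advance(start + block - step)
        step = start + block
        m = sim.sample()
        times.append(sim.time)
        for port in domain.outlets:
            out_flows[port.name].append(observables.plane_flow_rate(
                m.velocity, port.measure_comp, port.direction, units))
        for port in domain.inlets:
            in_flows[port.name].append(observables.plane_flow_rate(
                m.velocity, port.measure_comp, port.direction, units))

    times = np.asarray(times)
    outlet_series = {n: observables.OutletSeries(n, times, np.asarray(q))
                     for n, q in out_flows.items()}
    inlet_series = {n: observables.OutletSeries(n, times, np.asarray(q))
                    for n, q in in_flows.items()}
    return RunRecord(config=config, tau=tau, outlet_series=outlet_series,
                     inlet_series=inlet_series, snapshots=snapshots,
                     diagnostics=sim.log.to_dataframe(),
                     fluid_sites=domain.fluid_site_count)


def compare(healthy, stroke, smoothing_window=None,
            allow_geometry_mismatch=False):
    """Per-outlet stroke-to-healthy ratio report, ranked ascending.

    Returns (DataFrame with final-beat cycle-averaged ratios, dict of
    pointwise RatioSeries).  Both runs must share geometry, resolution and
    sampling cadence; pass ``allow_geometry_mismatch=True`` for the
    blocked-vessel corollary, where a variant's healthy flow is compared
    against the full circle's on the outlets they share.
    """
    ch, cs = healthy.config, stroke.config
    if (ch.dx != cs.dx or ch.resolved_dt() != cs.resolved_dt()
            or ch.cadence != cs.cadence):
        raise ConfigError(
            "healthy and stroke runs must share dx, dt and cadence")
    if ch.geometry != cs.geometry and not allow_geometry_mismatch:
        raise ConfigError(
            "healthy and stroke runs must share their geometry")
    if smoothing_window is None:
        smoothing_window = ch.period / 20.0
    import pandas as pd
    rows = []
    series = {}
    for name, hs in healthy.outlet_series.items():
        if name not in stroke.outlet_series:
            continue
        ss = stroke.outlet_series[name]
        series[name] = observables.flow_ratio(
            ss, hs, smoothing_window=smoothing_window)
        rows.append({
            "outlet": name,
            "final_beat_ratio": observables.final_beat_ratio(
                ss, hs, ch.period),
            "healthy_Q_mean": observables.cycle_average(hs, ch.period),
            "stroke_Q_mean": observables.cycle_average(ss, ch.period),
        })
    table = pd.DataFrame(rows).sort_values(
        "final_beat_ratio").reset_index(drop=True)
    return table, series


def experiment_matrix(base_config, scenarios=(1, 2, 3, 4, 5),
                      variants=("cow_full", "cow_no_pcoa_left",
                                "cow_no_pcoa_right")):
    """The full study: per variant, one healthy run plus one run per stroke
    scenario.  Returns {variant: {"healthy": record, scenario_id: record}}.
    Runs are independent; the domain is voxelized once per variant."""
    from dataclasses import replace
    results = {}
    for variant in variants:
        cfg_h = replace(base_config, geometry=variant, scenario=None)
        domain = build_domain(cfg_h)
        results[variant] = {"healthy": run(cfg_h, domain=domain)}
        for sid in scenarios:
            cfg_s = replace(base_config, geometry=variant, scenario=sid)
            results[variant][sid] = run(cfg_s, domain=domain)
    return results


def convergence_study(config, dx_list, analytic_q=None):
    """Steady-flow grid study: change in outlet flow between successive
    resolutions, plus error vs an analytic flow rate when available.

    Each dx uses a diffusively rescaled dt (dt ~ dx^2 at fixed tau).
    Returns a DataFrame with a ``grid_independent`` flag when the relative
    change drops to <= 2 %.
    """
    from dataclasses import replace
    if len(dx_list) < 2:
        raise ConfigError("need at least two resolutions")
    base_dt = config.resolved_dt()
    rows = []
    prev_q = None
    for dx in dx_list:
        dt = base_dt * (dx / config.dx) ** 2
        cfg = replace(config, dx=dx, dt=dt)
        rec = run(cfg)
        q = sum(observables.cycle_average(s, cfg.period)
                for s in rec.outlet_series.values())
        row = {"dx": dx, "total_outlet_Q": q,
               "fluid_sites": rec.fluid_sites}
        if prev_q is not None:
            change = abs(q - prev_q) / abs(prev_q)
            row["rel_change"] = change
            row["grid_independent"] = bool(change <= 0.02)
        if analytic_q is not None:
            row["rel_error_vs_analytic"] = abs(q - analytic_q) / abs(
                analytic_q)
        rows.append(row)
        prev_q = q
    import pandas as pd
    return pd.DataFrame(rows)


def save_checkpoint(sim, config, path):
    """Write populations + config hash to an HDF5 container."""
    import h5py
    with h5py.File(path, "w") as h5:
        h5.create_dataset("populations", data=sim.f)
        h5.attrs["step"] = sim.step_count
        h5.attrs["config_hash"] = config.config_hash()


def load_checkpoint(sim, config, path):
    import h5py
    with h5py.File(path, "r") as h5:
        if h5.attrs["config_hash"] != config.config_hash():
            raise ConfigError("checkpoint belongs to a different config")
        sim.f[...] = h5["populations"][...]
        sim.step_count = int(h5.attrs["step"])
    return sim
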