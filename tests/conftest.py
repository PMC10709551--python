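"""Shared fixtures: small voxel domains and the scaled-down circle-of-Willis
scenario-1 experiment (session-scoped; several tests interrogate it)."""

from dataclasses import replace

import numpy as np
import pytest

from willisflow import vessel_geometry as vg
from willisflow.pipeline import RunConfig, build_domain, run
from willisflow.waveforms import DEFAULT_PERIOD


@pytest.fixture(scope="session")
def tube_domain():
    """Straight tube, 16 sites per radius, with parabolic inlet weights."""
    R = 1.6e-3
    return vg.voxelize(vg.build_tube(R, 3 * R), R / 16)


@pytest.fixture(scope="session")
def closed_box():
    """Sealed box of fluid: walls on all six faces, no iolets."""
    labels = np.full((12, 12, 12), vg.SOLID, dtype=np.uint8)
    labels[1:-1, 1:-1, 1:-1] = vg.FLUID
    return vg.VoxelDomain.from_labels(labels, dx=1.0e-4)


def desk_cow_config(**overrides):
    """Desk-scale circle-of-Willis protocol used by the redistribution
    study: dx = 0.2 mm, viscous-regime inlet speeds, two beats with the
    stroke starting at the end of warm-up."""
    cfg = dict(
        geometry="cow_full", dx=2.0e-4, target_lattice_speed=0.04,
        peak_velocity={"BA": 0.024, "LICA": 0.03, "RICA": 0.03},
        warmup=0.3, duration=0.3 + 2 * DEFAULT_PERIOD, stroke_onset=0.3,
        cadence=5.0e-3)
    cfg.update(overrides)
    return RunConfig(**cfg)


@pytest.fixture(scope="session")
def cow_scenario1_results():
    """Healthy and sudden-halt (scenario 1) runs on all three variants.

    The expensive shared computation behind the flow-redistribution
    checks: {(variant, scenario): RunRecord} with scenario None = healthy.
    """
    base = desk_cow_config()
    results = {}
    for geom in ("cow_full", "cow_no_pcoa_left", "cow_no_pcoa_right"):
        domain = build_domain(replace(base, geometry=geom))
        for scen in (None, 1):
            cfg = replace(base, geometry=geom, scenario=scen)
            results[(geom, scen)] = run(cfg, domain=domain)
    return results
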