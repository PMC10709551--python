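"""Core solver: stencil identities, moments, collision, streaming, units."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from willisflow import vessel_geometry as vg
from willisflow.errors import InvalidParameterError, SimulationDivergedError
from willisflow.lbm_core import (CS2, D3Q19, Simulation, UnitSystem,
                                 collide_bgk, equilibrium, macroscopics,
                                 relaxation_time, stability_report, stream,
                                 step_reference, viscosity_from_tau)


class TestVelocitySet:
    def test_moment_identities_exact(self):
        """Weight normalization and second-moment isotropy hold in exact
        rational arithmetic."""
        w = D3Q19.weights_exact()
        c = D3Q19.directions
        assert sum(w) == Fraction(1)
        for a in range(3):
            assert sum(wi * int(ci[a]) for wi, ci in zip(w, c)) == 0
            for b in range(3):
                expect = Fraction(1, 3) if a == b else Fraction(0)
                assert sum(wi * int(ci[a]) * int(ci[b])
                           for wi, ci in zip(w, c)) == expect

    def test_opposite_is_fixed_point_free_involution(self):
        opp = D3Q19.opposite
        assert np.all(opp[opp] == np.arange(19))
        assert opp[0] == 0
        assert np.all(opp[1:] != np.arange(1, 19))
        assert np.all(D3Q19.directions[opp] == -D3Q19.directions)


class TestUnits:
    def test_roundtrip_is_identity(self):
        u = UnitSystem(dx=25e-6, dt=1e-6)
        v = 0.595
        assert u.velocity_to_physical(u.velocity_to_lattice(v)) == \
            pytest.approx(v, rel=1e-15)

    def test_invalid_scales_rejected(self):
        with pytest.raises(InvalidParameterError):
            UnitSystem(dx=-1e-6, dt=1e-6)


class TestRelaxationTime:
    def test_blood_at_reference_discretization(self):
        """Blood viscosity on the 25 um / 1 us lattice gives tau = 0.5192."""
        units = UnitSystem(dx=25e-6, dt=1e-6)
        assert relaxation_time(4.0e-6, units) == pytest.approx(0.5192,
                                                               abs=1e-12)

    def test_zero_viscosity_limit_and_unit_lattice_viscosity(self):
        units = UnitSystem(dx=1e-4, dt=1e-4)
        assert relaxation_time(1e-12, units) == pytest.approx(0.5, abs=1e-6)
        # lattice viscosity 1/6 (nu = dx^2/(6 dt)) -> tau = 1
        assert relaxation_time(units.dx ** 2 / (6 * units.dt), units) == \
            pytest.approx(1.0, rel=1e-14)

    @pytest.mark.parametrize("tau", [0.5192, 0.55, 0.8, 1.2])
    def test_viscosity_inverse(self, tau):
        units = UnitSystem(dx=25e-6, dt=1e-6)
        nu = viscosity_from_tau(tau, units)
        assert relaxation_time(nu, units) == pytest.approx(tau, rel=1e-14)

    def test_nonpositive_viscosity_rejected(self):
        with pytest.raises(InvalidParameterError):
            relaxation_time(-1e-6, UnitSystem(dx=1e-4, dt=1e-4))


class TestEquilibrium:
    def test_rest_state_gives_weights(self):
        f = equilibrium(1.0, np.zeros(3))
        assert np.allclose(f, D3Q19.weights, rtol=0, atol=1e-16)

    def test_hand_evaluated_values(self):
        """Direct evaluation at rho=1, u=(0.1,0,0) for the rest and +x
        directions."""
        f = equilibrium(1.0, np.array([0.1, 0.0, 0.0]))
        assert f[0] == pytest.approx((1 / 3) * (1 - 0.015), rel=1e-14)
        ix = int(np.nonzero((D3Q19.directions ==
                             [1, 0, 0]).all(axis=1))[0][0])
        assert f[ix] == pytest.approx((1 / 18) * (1 + 0.3 + 0.045 - 0.015),
                                      rel=1e-14)

    @given(rho=st.floats(0.5, 2.0),
           u=arrays(float, 3, elements=st.floats(-0.05, 0.05)))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_moments_recovered(self, rho, u):
        f = equilibrium(rho, u)
        m = macroscopics(f)
        assert m.density[0] == pytest.approx(rho, rel=1e-13)
        assert np.allclose(m.velocity[0], u, atol=1e-15)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(InvalidParameterError):
            equilibrium(-1.0, np.zeros(3))


class TestMacroscopics:
    def test_two_population_moment(self):
        """Only (+-1,0,0) carry mass 0.6/0.4: rho = 1, u_x = 0.2."""
        f = np.zeros(19)
        ip = int(np.nonzero((D3Q19.directions ==
                             [1, 0, 0]).all(axis=1))[0][0])
        im = int(D3Q19.opposite[ip])
        f[ip], f[im] = 0.6, 0.4
        m = macroscopics(f)
        assert m.density[0] == pytest.approx(1.0)
        assert m.velocity[0, 0] == pytest.approx(0.2)
        assert m.pressure[0] == pytest.approx(CS2)

    def test_nonpositive_density_diverges(self):
        with pytest.raises(SimulationDivergedError):
            macroscopics(np.zeros(19))


class TestCollision:
    def test_equilibrium_is_fixed_point(self):
        f = equilibrium(np.array([1.2]), np.array([[0.02, 0.0, -0.01]]))
        assert np.allclose(collide_bgk(f, 0.7), f, rtol=0, atol=1e-15)

    def test_full_relaxation_at_tau_one(self):
        rng = np.random.default_rng(7)
        f = equilibrium(np.ones(5), np.zeros((5, 3)))
        f *= 1.0 + 0.05 * rng.standard_normal(f.shape)
        m = macroscopics(f)
        assert np.allclose(collide_bgk(f, 1.0),
                           equilibrium(m.density, m.velocity), atol=1e-15)

    @given(pert=arrays(float, (19, 4), elements=st.floats(-0.01, 0.01)),
           tau=st.floats(0.51, 2.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_mass_and_momentum_conserved(self, pert, tau):
        f = equilibrium(np.ones(4), np.zeros((4, 3))) + pert
        out = collide_bgk(f, tau)
        assert np.allclose(out.sum(axis=0), f.sum(axis=0), rtol=1e-12)
        c = D3Q19.directions.astype(float)
        assert np.allclose(c.T @ out, c.T @ f, rtol=0, atol=1e-12)

    def test_nonfinite_populations_diverge(self):
        f = equilibrium(np.ones(3), np.zeros((3, 3)))
        f[5, 1] = np.nan
        with pytest.raises(SimulationDivergedError):
            collide_bgk(f, 0.8)


class TestStreaming:
    def test_single_population_advects_one_cell_per_step(self):
        dom = vg.periodic_box((8, 4, 4), dx=1.0)
        ix = int(np.nonzero((D3Q19.directions ==
                             [1, 0, 0]).all(axis=1))[0][0])
        f = np.zeros((19, dom.n_comp))
        start = int(np.nonzero((dom.comp_coords ==
                                [2, 1, 1]).all(axis=1))[0][0])
        f[ix, start] = 1.0
        f1 = stream(f, dom)
        one = int(np.nonzero((dom.comp_coords ==
                              [3, 1, 1]).all(axis=1))[0][0])
        assert f1[ix, one] == 1.0 and f1.sum() == 1.0
        two = int(np.nonzero((dom.comp_coords ==
                              [4, 1, 1]).all(axis=1))[0][0])
        assert stream(f1, dom)[ix, two] == 1.0

    def test_periodic_box_conserves_mass(self):
        dom = vg.periodic_box((6, 6, 6), dx=1.0)
        rng = np.random.default_rng(11)
        f = equilibrium(np.ones(dom.n_comp), np.zeros((dom.n_comp, 3)))
        f *= 1.0 + 0.1 * rng.standard_normal(f.shape)
        f1 = stream(f, dom)
        assert abs(f1.sum() - f.sum()) / f.sum() < 1e-14


class TestStabilityReport:
    def test_quiescent_passes(self):
        rep = stability_report(0.0, UnitSystem(dx=25e-6, dt=1e-6), tau=0.52)
        assert rep.mach == 0.0 and rep.passed

    def test_peak_cerebral_speed_on_reference_lattice(self):
        """0.595 m/s at 25 um / 1 us: lattice speed 0.0238, Ma ~ 0.041."""
        rep = stability_report(0.595, UnitSystem(dx=25e-6, dt=1e-6),
                               tau=0.5192)
        assert rep.lattice_speed == pytest.approx(0.0238, rel=1e-12)
        assert rep.mach == pytest.approx(0.0412, abs=5e-4)
        assert rep.passed

    def test_supersonic_always_fails(self):
        rep = stability_report(1.0, UnitSystem(dx=1e-6, dt=1e-5), tau=5.0,
                               mach_cap=1e9)
        assert not rep.passed


class TestSimulation:
    def test_quiescent_closed_box_is_invariant(self, closed_box):
        units = UnitSystem(dx=closed_box.dx, dt=1e-5)
        sim = Simulation(closed_box, units, tau=0.8)
        f0 = sim.f.copy()
        sim.advance(50)
        # invariant to rounding: sum(w_i) != 1 at the last ulp
        assert np.allclose(sim.f, f0, rtol=0, atol=1e-13)

    def test_deterministic_bitwise(self, closed_box):
        units = UnitSystem(dx=closed_box.dx, dt=1e-5)
        rng = np.random.default_rng(3)
        u0 = 0.01 * rng.standard_normal((closed_box.n_comp, 3))
        sims = []
        for _ in range(2):
            sim = Simulation(closed_box, units, tau=0.8,
                             initial_velocity=u0.copy())
            sim.advance(200)
            sims.append(sim.f.copy())
        assert np.array_equal(sims[0], sims[1])

    def test_shear_wave_mass_drift_below_1e10_per_1000_steps(self):
        dom = vg.periodic_box((32, 4, 4), dx=1.0)
        units = UnitSystem(dx=1.0, dt=1.0)
        u0 = np.zeros((dom.n_comp, 3))
        u0[:, 1] = 1e-3 * np.sin(2 * np.pi * (dom.comp_coords[:, 0] + 0.5)
                                 / 32)
        sim = Simulation(dom, units, tau=0.8, initial_velocity=u0)
        m0 = sim.f.sum()
        sim.advance(1000)
        assert abs(sim.f.sum() - m0) / m0 < 1e-10

    def test_divergence_raises_located_error(self, closed_box):
        units = UnitSystem(dx=closed_box.dx, dt=1e-5)
        sim = Simulation(closed_box, units, tau=0.8, check_interval=10)
        sim.f[0, 5] = np.nan
        with pytest.raises(SimulationDivergedError) as e:
            sim.advance(20)
        assert e.value.step is not None and e.value.site is not None


class TestKernelAgainstReferencePath:
    def test_fused_step_matches_numpy_operations(self, tube_domain):
        """One kernel step equals collide + stream + boundary resolvers
        composed in the documented order, on a driven tube."""
        dom = tube_domain
        units = UnitSystem(dx=dom.dx, dt=1e-5)
        tau = 0.8
        rng = np.random.default_rng(5)
        u0 = 0.005 * rng.standard_normal((dom.n_comp, 3))
        sim = Simulation(dom, units, tau,
                         inlet_velocity={dom.port("in").id:
                                         lambda t: 0.02 * units.velocity},
                         initial_velocity=u0)
        f0 = sim.f.copy()
        ub = sim._inlet_ub(0.0)
        expected = step_reference(f0, dom, tau, ub, np.ones(1))
        sim.advance(1)
        assert np.allclose(sim.f, expected, rtol=1e-13, atol=1e-16)
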