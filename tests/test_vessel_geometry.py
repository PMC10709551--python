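"""Synthetic vessel networks, voxelization and inlet weighting."""

import numpy as np
import pytest

from willisflow import vessel_geometry as vg
from willisflow.errors import GeometryError


class TestBuilders:
    def test_tube_has_one_inlet_one_outlet(self):
        net = vg.build_tube(1.6e-3, 8e-3)
        assert net.inlet_names == ["in"] and net.outlet_names == ["out"]

    def test_nonpositive_tube_dimensions_rejected(self):
        with pytest.raises(GeometryError):
            vg.build_tube(-1e-3, 8e-3)

    def test_bifurcation_mirror_symmetric(self):
        net = vg.build_symmetric_bifurcation(1.6e-3, 1.2e-3, np.pi / 4)
        mirrored = net.mirrored(axis=0, center=0.0)
        by_label = {s.label: s for s in net.segments}
        swap = {"daughter-left": "daughter-right",
                "daughter-right": "daughter-left",
                "riser-left": "riser-right", "riser-right": "riser-left"}
        for s in mirrored.segments:
            ref = by_label[swap.get(s.label, s.label)]
            assert np.allclose(s.start, ref.start)
            assert np.allclose(s.end, ref.end)
            assert s.radius == ref.radius

    def test_degenerate_daughter_angle_refused(self):
        with pytest.raises(GeometryError):
            vg.build_symmetric_bifurcation(1.6e-3, 1.2e-3, 0.0)
        with pytest.raises(GeometryError):
            vg.build_symmetric_bifurcation(1.6e-3, 1.2e-3, 0.05)

    def test_cow_full_topology(self):
        net = vg.build_idealized_cow(vg.CoWVariant.FULL)
        assert sorted(net.inlet_names) == ["BA", "LICA", "RICA"]
        assert sorted(net.outlet_names) == ["LACA", "LMCA", "LPCA",
                                            "RACA", "RMCA", "RPCA"]
        labels = {s.label for s in net.segments}
        assert {"PCoA-L", "PCoA-R", "ACoA", "P1-L", "P1-R",
                "A1-L", "A1-R"} <= labels

    def test_cow_variant_removes_one_pcoa_only(self):
        full = vg.build_idealized_cow(vg.CoWVariant.FULL)
        nr = vg.build_idealized_cow(vg.CoWVariant.NO_PCOA_RIGHT)
        assert {s.label for s in full.segments} - \
            {s.label for s in nr.segments} == {"PCoA-R"}
        assert sorted(nr.outlet_names) == sorted(full.outlet_names)

    def test_cow_mirror_symmetry_up_to_label_swap(self):
        net = vg.build_idealized_cow(vg.CoWVariant.FULL)
        mirrored = net.mirrored(axis=0, center=10.0e-3)

        def side_swap(lbl):
            table = str.maketrans({"L": "R", "R": "L"})
            return lbl.translate(table)

        by_label = {s.label: s for s in net.segments}
        for s in mirrored.segments:
            ref = by_label.get(side_swap(s.label)) or by_label[s.label]
            assert np.allclose(s.start, ref.start) or \
                np.allclose(s.start, ref.end)
            assert s.radius == ref.radius

    def test_removing_unflagged_segment_refused(self):
        net = vg.build_idealized_cow(vg.CoWVariant.FULL)
        with pytest.raises(GeometryError):
            net.remove("BA")


class TestVoxelize:
    def test_tube_fluid_count_matches_cylinder_volume(self):
        """Site count within 5% of pi R^2 L / dx^3 for a 20-site radius."""
        R, L = 2.0e-3, 10.0e-3
        dx = R / 20
        dom = vg.voxelize(vg.build_tube(R, L), dx)
        expect = np.pi * R ** 2 * L / dx ** 3
        assert abs(dom.fluid_site_count - expect) / expect < 0.05

    def test_under_resolved_radius_refused_with_required_dx(self):
        with pytest.raises(GeometryError, match="need dx"):
            vg.voxelize(vg.build_tube(1.0e-3, 5e-3), dx=0.5e-3)

    def test_variant_has_fewer_fluid_sites_than_full(self):
        dx = 2.0e-4
        full = vg.voxelize(vg.build_idealized_cow(vg.CoWVariant.FULL), dx)
        left = vg.voxelize(
            vg.build_idealized_cow(vg.CoWVariant.NO_PCOA_LEFT), dx)
        assert left.fluid_site_count < full.fluid_site_count

    def test_variant_removal_is_local_to_the_removed_capsule(self):
        """Label differences are confined to the removed segment's capsule
        (plus its blending layer into the junctions)."""
        dx = 2.0e-4
        full = vg.voxelize(vg.build_idealized_cow(vg.CoWVariant.FULL), dx)
        left = vg.voxelize(
            vg.build_idealized_cow(vg.CoWVariant.NO_PCOA_LEFT), dx)
        diff = np.argwhere(full.labels != left.labels)
        pos = full.site_centers(diff)
        seg = next(s for s in
                   vg.build_idealized_cow(vg.CoWVariant.FULL).segments
                   if s.label == "PCoA-L")
        p0, p1 = np.asarray(seg.start), np.asarray(seg.end)
        e = (p1 - p0) / np.linalg.norm(p1 - p0)
        t = np.clip((pos - p0) @ e, 0, np.linalg.norm(p1 - p0))
        d = np.linalg.norm(pos - (p0 + t[:, None] * e[None, :]), axis=1)
        assert np.all(d <= seg.radius + 1.5 * dx)

    def test_disconnected_network_refused(self):
        far = vg.SegmentSpec((0, 0.02, 0.01), (0, 0.025, 0.01), 1e-3,
                             label="floater")
        near = vg.SegmentSpec((0, 0, 0), (0, 5e-3, 0), 1e-3, label="main")
        net = vg.VesselNetworkSpec(segments=(near, far))
        with pytest.raises(GeometryError, match="disconnected"):
            vg.voxelize(net, 2.5e-4)

    def test_iolet_sites_planar_with_fluid_interior_neighbour(self):
        dom = vg.voxelize(vg.build_tube(1.6e-3, 5e-3), 2e-4)
        for port in dom.inlets + dom.outlets:
            assert len(np.unique(port.coords[:, port.axis])) == 1
            assert np.all(port.measure_comp >= 0)

    def test_fluid_region_19_connected_padding_present(self):
        dom = vg.voxelize(vg.build_tube(1.6e-3, 5e-3), 2e-4)
        lab = dom.labels
        assert np.all(lab[0] == vg.SOLID) and np.all(lab[-1] == vg.SOLID)
        assert np.all(lab[:, 0] == vg.SOLID) and np.all(lab[:, :, 0] ==
                                                        vg.SOLID)

    def test_mask_roundtrip(self, tmp_path, tube_domain):
        path = tmp_path / "tube.npz"
        tube_domain.save_mask(path)
        back = vg.VoxelDomain.load_mask(path)
        assert np.array_equal(back.labels, tube_domain.labels)
        assert [p.name for p in back.inlets] == \
            [p.name for p in tube_domain.inlets]
        assert np.array_equal(back.pull, tube_domain.pull)


class TestInletWeighting:
    def test_center_distance_close_to_radius(self, tube_domain):
        """Brute-force nearest-solid search: the most central inlet site
        lies about one radius from the wall."""
        R = 1.6e-3
        d = vg.inlet_wall_distance(tube_domain, tube_domain.port("in").id)
        assert d.max() == pytest.approx(R, rel=0.1)
        assert d.min() < 2 * tube_domain.dx

    def test_distances_invariant_under_quarter_turn(self, tube_domain):
        """The circular cap's distance multiset is symmetric under an
        in-plane 90-degree rotation."""
        port = tube_domain.port("in")
        d = vg.inlet_wall_distance(tube_domain, port.id)
        centers = tube_domain.site_centers(port.coords)
        key = {(round(x, 9), round(z, 9)): dd
               for (x, _, z), dd in zip(centers, d)}
        for (x, z), dd in list(key.items()):
            assert key[(round(-z, 9), round(x, 9))] == pytest.approx(dd)

    def test_weight_endpoints(self):
        d = np.array([0.0, 0.5, 1.0])
        w = vg.inlet_weights(d)
        assert w[0] == 0.0 and w[-1] == 1.0
        assert np.all((0 <= w) & (w <= 1))

    def test_circular_cap_reconstructs_poiseuille_parabola(self,
                                                           tube_domain):
        """w(r) = 1 - (r/R)^2 when distances are measured to the cap rim."""
        R = 1.6e-3
        port = tube_domain.port("in")
        centers = tube_domain.site_centers(port.coords)
        r = np.hypot(centers[:, 0], centers[:, 2])
        w = tube_domain.inlet_weights[tube_domain.inlet_slice(port.id)]
        assert np.allclose(w, 1.0 - (r / R) ** 2, atol=1e-12)

    def test_all_sites_at_wall_rejected(self):
        with pytest.raises(GeometryError):
            vg.inlet_weights(np.zeros(4))
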