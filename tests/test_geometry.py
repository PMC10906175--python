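"""Synthetic geometry generator: surfaces, offset, solidify, trabeculae,
benchmarks, refinement series, quality."""

import numpy as np
import pytest

from laasnap import geometry as geo


class TestInnerSurface:
    def test_unperturbed_tube_axisymmetry(self):
        p = geo.preset_params("tube")
        s = geo.generate_inner_surface(p)
        r = np.linalg.norm(s.vertices[:, :2], axis=1)
        expect = geo.radius_profile(p, s.param_coords[:, 0])
        # exclude apex and base-center vertices (on the axis)
        dev = np.abs(r[:-2] - expect[:-2])
        assert dev.max() < 1e-9

    def test_determinism(self):
        p = geo.preset_params("cactus", seed=11)
        a = geo.generate_inner_surface(p)
        b = geo.generate_inner_surface(p)
        assert a.vertices.tobytes() == b.vertices.tobytes()
        assert np.array_equal(a.triangles, b.triangles)

    @pytest.mark.parametrize("preset", ["chicken_wing", "cactus", "windsock",
                                        "cauliflower"])
    def test_watertight_euler(self, preset):
        s = geo.generate_inner_surface(
            geo.preset_params(preset, seed=42, target_edge_length=2.0))
        assert s.is_watertight()
        assert s.euler_characteristic() == 2
        assert not s.has_degenerate_triangles()

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError):
            geo.MorphologyParams("tube", orifice_diameter=0.0, height=10.0)
        with pytest.raises(ValueError):
            geo.MorphologyParams("tube", orifice_diameter=10.0, height=-1.0)
        with pytest.raises(ValueError):
            geo.MorphologyParams("tube", orifice_diameter=10.0, height=10.0,
                                 taper_ratio=1.5)


class TestOffset:
    def test_sphere_offset_exact(self):
        s = geo.uv_sphere(10.0, 1.25)
        o = geo.offset_surface(s, 2.1, check=False)
        r = np.linalg.norm(o.vertices, axis=1)
        assert np.abs(r - 12.1).max() < 1e-9

    def test_zero_thickness_identity(self):
        s = geo.uv_sphere(5.0, 1.5)
        o = geo.offset_surface(s, 0.0, check=False)
        assert np.array_equal(o.vertices, s.vertices)

    def test_mean_wall_distance(self):
        p = geo.preset_params("chicken_wing", target_edge_length=2.0)
        inner = geo.generate_inner_surface(p)
        outer = geo.offset_surface(inner, 2.1, check=False)
        d = geo.offset_distances(inner, outer, sample=300)
        assert abs(d.mean() - 2.1) / 2.1 < 0.02

    def test_self_intersection_detected(self):
        # two interpenetrating spheres in one soup must report pairs
        a = geo.uv_sphere(5.0, 1.5)
        b = geo.uv_sphere(5.0, 1.5)
        verts = np.vstack([a.vertices, b.vertices + [4.0, 0, 0]])
        tris = np.vstack([a.triangles, b.triangles + a.n_vertices])
        bad = geo.check_self_intersections(geo.SurfaceMesh(verts, tris))
        assert len(bad) > 0


class TestSolidify:
    def test_prism_split_count(self):
        p = geo.preset_params("tube", target_edge_length=2.0)
        inner = geo.generate_inner_surface(p)
        outer = geo.offset_surface(inner, 2.1, check=False)
        mesh = geo.solidify(inner, outer)
        n_wall_tris = inner.n_triangles - len(inner.cap_faces)
        assert mesh.n_elements == 3 * n_wall_tris

    def test_positive_volumes_and_conformity(self):
        sh = geo.sphere_shell(8.0, 2.1, 1.6)
        assert np.all(sh.tet_volumes() > 0)
        assert geo.quality_report(sh).watertight

    def test_shell_volume_analytic(self):
        sh = geo.sphere_shell(10.0, 2.1, 1.25)
        exact = 4 * np.pi / 3 * (12.1 ** 3 - 10.0 ** 3)
        assert abs(sh.tet_volumes().sum() / exact - 1) < 0.02

    def test_orifice_ring_nonempty_on_outer_wall(self, coarse_wing):
        assert len(coarse_wing.orifice_ring) > 0
        # ring nodes sit near the orifice plane z ~ 0, on the outer side
        ring = coarse_wing.nodes[coarse_wing.orifice_ring]
        assert np.abs(ring[:, 2]).max() < 3.0


class TestTrabeculae:
    def test_zero_count_identity(self):
        p = geo.preset_params("cauliflower", target_edge_length=2.5)
        inner = geo.generate_inner_surface(p)
        outer = geo.offset_surface(inner, 2.1, check=False)
        mesh = geo.solidify(inner, outer)
        out = geo.add_trabeculae(mesh, p)
        assert out is mesh
        assert not out.trabecula_cables

    def test_windsock_small_diameters(self):
        m = geo.build_appendage(
            geo.preset_params("windsock", target_edge_length=2.5, n_layers=1))
        dias = [d for _, _, d in m.trabecula_cables]
        assert dias and all(0.8 <= d <= 1.2 for d in dias)

    def test_cactus_cable_geometry(self):
        m = geo.build_appendage(
            geo.preset_params("cactus", seed=5, target_edge_length=2.5,
                              n_layers=1))
        surf = set(m.node_sets["inner_surface"].tolist())
        span = np.ptp(m.nodes, axis=0).max()
        assert m.trabecula_cables
        for a, b, d in m.trabecula_cables:
            assert a in surf and b in surf
            assert 0 < np.linalg.norm(m.nodes[a] - m.nodes[b]) < span
            assert 2.0 <= d <= 4.3

    def test_overall_diameter_range(self):
        # across presets, diameters respect the observed 0.8-4.3 mm span
        all_d = []
        for name in ("chicken_wing", "cactus", "windsock"):
            m = geo.build_appendage(geo.preset_params(
                name, target_edge_length=2.8, n_layers=1))
            all_d += [d for _, _, d in m.trabecula_cables]
        assert all(0.8 <= d <= 4.3 for d in all_d)


class TestBenchmarks:
    def test_cap_rim_at_half_angle(self):
        cap = geo.make_benchmark("spherical_cap", radius=10.0, thickness=1.0,
                                 half_angle=60.0, edge=1.0)
        ring = cap.nodes[cap.orifice_ring]
        # outer-surface rim: radial offset preserves the polar angle
        ang = np.degrees(np.arccos(ring[:, 2] / np.linalg.norm(ring, axis=1)))
        assert np.allclose(ang, 60.0, atol=1e-6)

    def test_cap_half_angle_validation(self):
        with pytest.raises(ValueError):
            geo.make_benchmark("spherical_cap", half_angle=95.0)

    def test_tube_inner_area_analytic(self):
        tube = geo.make_benchmark("closed_tube", radius=5.0, thickness=1.0,
                                  length=25.0, edge=1.5)
        area = geo.SurfaceMesh(tube.nodes, tube.inner_facets).area()
        exact = 2 * np.pi * 5.0 * 25.0 + np.pi * 5.0 ** 2
        assert abs(area / exact - 1) < 0.03

    def test_cap_count_scales_with_edge(self):
        c1 = geo.make_benchmark("spherical_cap", radius=10.0, thickness=1.0,
                                half_angle=60.0, edge=1.0)
        c2 = geo.make_benchmark("spherical_cap", radius=10.0, thickness=1.0,
                                half_angle=60.0, edge=0.5)
        assert c2.n_elements / c1.n_elements == pytest.approx(4.0, rel=0.15)


class TestSeries:
    def test_twenty_percent_increments(self):
        series = geo.mesh_series(
            geo.preset_params("chicken_wing", target_edge_length=2.8,
                              n_layers=1), n=3, increment=0.20)
        c = [m.n_elements for m in series]
        assert c[0] < c[1] < c[2]
        assert 1.15 <= c[1] / c[0] <= 1.25
        assert 1.15 <= c[2] / c[1] <= 1.25

    def test_zero_increment_equal_counts(self):
        series = geo.mesh_series(
            geo.preset_params("tube", target_edge_length=2.0, n_layers=1),
            n=2, increment=0.0)
        c = [m.n_elements for m in series]
        assert abs(c[1] / c[0] - 1) <= 0.05

    def test_series_determinism(self):
        p = geo.preset_params("windsock", target_edge_length=2.8, n_layers=1,
                              seed=3)
        s1 = geo.mesh_series(p, n=2, increment=0.2)
        s2 = geo.mesh_series(p, n=2, increment=0.2)
        for a, b in zip(s1, s2):
            assert a.nodes.tobytes() == b.nodes.tobytes()


class TestQuality:
    def test_regular_tet(self):
        a = 1.0
        nodes = np.array([[0, 0, 0], [a, 0, 0], [a / 2, a * np.sqrt(3) / 2, 0],
                          [a / 2, a * np.sqrt(3) / 6, a * np.sqrt(2.0 / 3)]])
        mesh = geo.VolumeMesh(nodes, np.array([[0, 1, 2, 3]]),
                              np.empty((0, 3), np.int64),
                              np.empty(0, np.int64))
        rep = geo.quality_report(mesh)
        assert rep.min_edge == pytest.approx(1.0, rel=1e-9)
        assert rep.max_edge == pytest.approx(1.0, rel=1e-9)
        assert rep.min_scaled_jacobian == pytest.approx(1.0, rel=1e-9)

    def test_default_wing_edge_statistics(self):
        mesh = geo.build_appendage(geo.preset_params("chicken_wing"))
        rep = geo.quality_report(mesh)
        assert 1.0 <= rep.mean_edge <= 1.5
        assert 0.1 <= rep.min_edge <= 0.5
        assert rep.n_elements == mesh.n_elements
        assert rep.watertight
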