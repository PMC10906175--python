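"""Explicit solver: masses, forces, loads, cables, contact, integration,
energy bookkeeping."""

import numpy as np
import pytest

from laasnap import fem, geometry as geo, ogden
from laasnap import protocol as proto
from laasnap.units import mmhg_to_mpa


class TestLumpedMass:
    def test_single_tet_quarter_mass(self, single_tet):
        m = fem.lumped_mass(single_tet, 1120.0)
        V = single_tet.tet_volumes()[0]
        assert np.allclose(m, 1120e-12 * V / 4)

    def test_total_mass_conserved(self, small_shell):
        m = fem.lumped_mass(small_shell, 1120.0)
        assert m.sum() == pytest.approx(
            1120e-12 * small_shell.tet_volumes().sum(), rel=1e-12)

    def test_mass_scaling_doubles_dt(self, small_shell, mat):
        dt1 = fem.stable_time_increment(small_shell, mat,
                                        fem.ExplicitConfig())
        dt4 = fem.stable_time_increment(
            small_shell, mat, fem.ExplicitConfig(mass_scaling=4.0))
        assert dt4 == pytest.approx(2 * dt1, rel=1e-12)


class TestStableTimeIncrement:
    def test_halving_edges_halves_dt(self, small_shell, mat):
        cfg = fem.ExplicitConfig()
        dt1 = fem.stable_time_increment(small_shell, mat, cfg)
        half = geo.VolumeMesh(0.5 * small_shell.nodes, small_shell.tets,
                              small_shell.inner_facets,
                              small_shell.orifice_ring)
        assert fem.stable_time_increment(half, mat, cfg) == pytest.approx(
            dt1 / 2, rel=1e-12)

    def test_characteristic_length_over_wave_speed(self, mat, single_tet):
        # undamped, unit safety: dt = min altitude / c_d; at Le = 0.1 mm and
        # the tissue card's c_d the transit time is about 7e-6 s
        cfg = fem.ExplicitConfig(dt_safety=1.0, b1=0.0)
        dt = fem.stable_time_increment(single_tet, mat, cfg)
        V = single_tet.tet_volumes()[0]
        x = single_tet.nodes[single_tet.tets[0]]
        amax = max(
            0.5 * np.linalg.norm(np.cross(x[b] - x[a], x[c] - x[a]))
            for a, b, c in [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)])
        le = 3 * V / amax
        cd = ogden.initial_moduli(mat)["c_d"]
        assert dt == pytest.approx(le / cd, rel=1e-12)
        assert 0.1 / cd == pytest.approx(7.1e-6, rel=0.01)


class TestInternalForces:
    def test_zero_at_rest(self, small_shell, mat):
        f = fem.internal_forces(small_shell, mat,
                                np.zeros((small_shell.n_nodes, 3)))
        assert np.abs(f).max() < 1e-12

    def test_rigid_translation_invariance(self, small_shell, mat):
        u = np.tile([1.7, -0.4, 2.2], (small_shell.n_nodes, 1))
        assert np.abs(fem.internal_forces(small_shell, mat, u)).max() < 1e-10

    def test_rigid_rotation_invariance(self, small_shell, mat):
        c, s = np.cos(0.5), np.sin(0.5)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        u = small_shell.nodes @ R.T - small_shell.nodes
        assert np.abs(fem.internal_forces(small_shell, mat, u)).max() < 1e-10

    def test_single_tet_energy_gradient(self, single_tet, mat):
        rng = np.random.default_rng(0)
        u = 0.05 * rng.standard_normal((4, 3))
        f = fem.internal_forces(single_tet, mat, u)
        h = 1e-7
        fd = np.zeros_like(f)
        for a in range(4):
            for i in range(3):
                up, um = u.copy(), u.copy()
                up[a, i] += h
                um[a, i] -= h
                fd[a, i] = -(fem.strain_energy(single_tet, mat, up)
                             - fem.strain_energy(single_tet, mat, um)) / (2 * h)
        scale = np.abs(f).max()
        assert np.abs(f - fd).max() < 1e-6 * scale

    def test_assembled_energy_gradient(self, small_shell, mat):
        rng = np.random.default_rng(1)
        u = 0.02 * rng.standard_normal((small_shell.n_nodes, 3))
        f = fem.internal_forces(small_shell, mat, u)
        h = 1e-7
        for a, i in [(3, 0), (40, 1), (150, 2)]:
            up, um = u.copy(), u.copy()
            up[a, i] += h
            um[a, i] -= h
            fd = -(fem.strain_energy(small_shell, mat, up)
                   - fem.strain_energy(small_shell, mat, um)) / (2 * h)
            assert f[a, i] == pytest.approx(fd, abs=1e-6 * np.abs(f).max())

    def test_inverted_element_reported(self, single_tet, mat):
        u = np.zeros((4, 3))
        u[3, 2] = -2.0   # push apex through the base plane
        with pytest.raises(fem.ElementInversionError) as ei:
            fem.internal_forces(single_tet, mat, u)
        assert ei.value.element == 0


class TestBulkViscosity:
    def test_zero_rate(self):
        assert fem.bulk_viscosity_pressure(0.0, 14000.0, 1.0, 1.12e-9) == 0.0

    def test_expansion_linear_only(self):
        rho, cd, le = 1.12e-9, 14000.0, 1.0
        q = fem.bulk_viscosity_pressure(2.0, cd, le, rho, b1=0.06, b2=1.2)
        assert q == pytest.approx(0.06 * rho * cd * le * 2.0)
        assert q > 0.0   # same sign as the rate: dissipative

    def test_quadratic_scaling_in_compression(self):
        rho, cd, le = 1.12e-9, 14000.0, 1.0
        lin = lambda r: 0.06 * rho * cd * le * r
        q1 = fem.bulk_viscosity_pressure(-1.0, cd, le, rho) - lin(-1.0)
        q2 = fem.bulk_viscosity_pressure(-2.0, cd, le, rho) - lin(-2.0)
        assert q2 == pytest.approx(4 * q1, rel=1e-12)


class TestFollowerPressure:
    def test_closed_surface_zero_net_force(self, small_shell):
        f = fem.follower_pressure_forces(
            small_shell, np.zeros((small_shell.n_nodes, 3)), 10.0)
        a_tot = geo.SurfaceMesh(small_shell.nodes,
                                small_shell.inner_facets).area()
        p = mmhg_to_mpa(10.0)
        assert np.linalg.norm(f.sum(axis=0)) < 1e-10 * p * a_tot

    def test_single_triangle_split(self):
        nodes = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0.0]])
        mesh = geo.VolumeMesh(nodes, np.empty((0, 4), np.int64),
                              np.array([[0, 1, 2]]), np.empty(0, np.int64))
        f = fem.follower_pressure_forces(mesh, np.zeros((3, 3)), 5.0)
        p = mmhg_to_mpa(5.0)
        expected = p * 2.0 / 3.0    # area 2, n = +z, split over 3 nodes
        assert np.allclose(f[:, 2], expected)
        assert np.allclose(f[:, :2], 0.0)

    def test_inflation_work_matches_p_dV(self, mat):
        shell = geo.sphere_shell(6.0, 1.5, 2.5)
        protocol = proto.PressureProtocol(times=(0.0, 0.05, 0.25),
                                          pressures=(0.0, 0.04, 0.04),
                                          stage_bounds=(0.0, 0.25))
        cfg = fem.ExplicitConfig(mass_damping=150.0, mass_scaling=25.0,
                                 output_interval=1e-3)
        res = fem.run_protocol(shell, mat, protocol, cfg)
        tr = res.trace
        p_mpa = mmhg_to_mpa(tr.pressure)
        pdv = np.sum(0.5 * (p_mpa[1:] + p_mpa[:-1])
                     * np.diff(tr.cavity_volume))
        assert tr.external_work[-1] == pytest.approx(pdv, rel=0.01)


class TestTrabeculaForces:
    def _cable_mesh(self, stretch, diameter=2.0):
        L0 = 10.0
        nodes = np.array([[0, 0, 0], [0, 0, L0 * stretch]])
        mesh = geo.VolumeMesh(nodes, np.empty((0, 4), np.int64),
                              np.empty((0, 3), np.int64),
                              np.empty(0, np.int64),
                              trabecula_cables=[(0, 1, diameter)])
        mesh.nodes = np.array([[0, 0, 0], [0, 0, L0]], float)
        u = np.array([[0, 0, 0], [0, 0, L0 * (stretch - 1)]], float)
        return mesh, u

    def test_unit_stretch_zero(self, mat):
        mesh, u = self._cable_mesh(1.0)
        f, fmax = fem.trabecula_forces(mesh, mat, u)
        assert fmax == 0.0 and np.allclose(f, 0.0)

    def test_closed_form_magnitude(self, mat):
        mesh, u = self._cable_mesh(1.1, diameter=2.0)
        f, fmax = fem.trabecula_forces(mesh, mat, u)
        P = ogden.uniaxial_nominal_stress(mat, 1.1)
        assert fmax == pytest.approx(P * np.pi, rel=1e-12)
        # tension pulls the far node back toward the anchor
        assert f[1, 2] == pytest.approx(-P * np.pi, rel=1e-12)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-15)

    def test_tension_only(self, mat):
        mesh, u = self._cable_mesh(0.8)
        f, fmax = fem.trabecula_forces(mesh, mat, u)
        assert fmax == 0.0 and np.allclose(f, 0.0)


class TestContact:
    def test_separated_no_force(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.2, 0.2, 5.0]])
        facets = np.array([[0, 1, 2]])
        pairs = np.array([[3, 0]])
        f = np.zeros((4, 3))
        E, clear = fem._contact_pass(x, pairs, facets, 0.5, 1.0,
                                     np.ones(4), f)
        assert E == 0.0 and np.abs(f).max() == 0.0
        assert clear == pytest.approx(5.0)

    def test_penetration_newton_third_law(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.2, 0.2, 0.1]])
        facets = np.array([[0, 1, 2]])
        pairs = np.array([[3, 0]])
        f = np.zeros((4, 3))
        k, offset, trib = 2.0, 0.5, np.full(4, 1.5)
        E, _ = fem._contact_pass(x, pairs, facets, offset, k, trib, f)
        pen = offset - 0.1
        assert f[3, 2] == pytest.approx(k * 1.5 * pen)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-14)
        assert E == pytest.approx(0.5 * k * 1.5 * pen ** 2)


class TestAdvance:
    def test_rest_stays_at_rest(self):
        u = np.zeros((3, 3))
        v = np.zeros((3, 3))
        u2, v2 = fem.advance(u, v, np.zeros((3, 3)), np.ones(3), 1e-3)
        assert np.all(u2 == 0) and np.all(v2 == 0)

    def test_constant_force_discrete_quadratic(self):
        m, F, dt, n = 2.0, 3.0, 0.1, 12
        u = np.zeros((1, 3))
        v = np.zeros((1, 3))
        forces = np.array([[F, 0, 0]])
        for _ in range(n):
            u, v = fem.advance(u, v, forces, np.array([m]), dt)
        # central difference from rest: u_n = (F/m) dt^2 n(n+1)/2
        assert u[0, 0] == pytest.approx(F / m * dt * dt * n * (n + 1) / 2,
                                        rel=1e-12)

    def test_pinned_node(self):
        u = np.zeros((2, 3))
        v = np.zeros((2, 3))
        forces = np.ones((2, 3))
        u2, v2 = fem.advance(u, v, forces, np.ones(2), 0.1,
                             pinned=np.array([0]))
        assert np.all(u2[0] == 0) and np.all(v2[0] == 0)
        assert np.all(u2[1] != 0)


class TestRunProtocol:
    def test_zero_pressure_equilibrium(self, mat):
        cap = geo.make_benchmark("spherical_cap", radius=8.0, thickness=1.0,
                                 half_angle=50.0, edge=2.0)
        res = fem.run_protocol(cap, mat, proto.zero_protocol(0.01),
                               fem.ExplicitConfig(output_interval=2e-3))
        assert not res.aborted
        assert np.abs(res.u).max() < 1e-12

    def test_momentum_conservation_closed_cavity(self, mat):
        shell = geo.sphere_shell(6.0, 1.5, 2.5)
        protocol = proto.PressureProtocol(times=(0.0, 0.02, 0.05),
                                          pressures=(0.0, 0.05, 0.05),
                                          stage_bounds=(0.0, 0.05))
        cfg = fem.ExplicitConfig(mass_scaling=16.0, output_interval=5e-3)
        res = fem.run_protocol(shell, mat, protocol, cfg)
        m = fem.lumped_mass(shell, mat.density, 16.0)
        p_net = np.abs((m[:, None] * res.v).sum(axis=0)).max()
        # impulse scale: |p| * area * time
        scale = mmhg_to_mpa(0.05) * 4 * np.pi * 36 * 0.05
        assert p_net < 1e-8 * scale

    def test_deterministic_rerun(self, mat):
        cap = geo.make_benchmark("spherical_cap", radius=8.0, thickness=1.0,
                                 half_angle=50.0, edge=2.0)
        protocol = proto.standard_protocol().scaled(pressure=0.05, time=0.005)
        cfg = fem.ExplicitConfig(mass_scaling=16.0, output_interval=2e-3)
        r1 = fem.run_protocol(cap, mat, protocol, cfg)
        r2 = fem.run_protocol(cap, mat, protocol, cfg)
        assert r1.u.tobytes() == r2.u.tobytes()
        assert np.array_equal(r1.trace.strain, r2.trace.strain)

    def test_energy_audit_on_cap_cycle(self, cap_cycle):
        tr = cap_cycle["result"].trace
        residual = np.abs(tr.external_work
                          - (tr.strain + tr.kinetic + tr.viscous
                             + tr.contact))
        assert residual.max() <= 0.02 * tr.strain.max()

    def test_snapshots_at_stage_bounds(self, cap_cycle):
        res = cap_cycle["result"]
        protocol = cap_cycle["protocol"]
        assert len(res.snapshots) == len(protocol.stage_bounds)
        np.testing.assert_allclose(res.snapshot_times,
                                   protocol.stage_bounds, rtol=1e-9)


class TestStressField:
    def test_hydrostatic_state(self, single_tet, mat):
        s = 0.99   # uniform compression
        u = single_tet.nodes * s - single_tet.nodes
        field = fem.max_principal_stress_field(single_tet, mat, u)
        expected = 2.0 * (s ** 3 - 1.0) / mat.D[0]
        assert field[0] == pytest.approx(expected, rel=1e-9)

    def test_uniaxial_state_matches_material_point(self, single_tet, mat):
        lam = 1.2
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        u = single_tet.nodes @ F.T - single_tet.nodes
        field = fem.max_principal_stress_field(single_tet, mat, u)
        sig = ogden.cauchy_stress(mat, F)
        assert field[0] == pytest.approx(np.linalg.eigvalsh(sig).max(),
                                        rel=1e-9)
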