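"""Snap-event detection, pressures, orifice frame, protrusion,
classification."""

import numpy as np
import pytest

from laasnap import fem, geometry as geo, metrics


def make_trace(time, strain, pressure):
    n = len(time)
    z = np.zeros(n)
    return fem.EnergyTrace(
        time=np.asarray(time, float), pressure=np.asarray(pressure, float),
        strain=np.asarray(strain, float), kinetic=z, viscous=z, contact=z,
        external_work=z, cavity_volume=z, max_cable_force=z,
        tip_centroid=np.zeros((n, 3)),
        kinetic_fraction_flags=np.zeros(n, bool))


class TestDetector:
    def test_smooth_trace_no_events(self):
        t = np.linspace(0, 1, 200)
        tr = make_trace(t, 5 * t ** 2, -100 * t)
        assert metrics.detect_snap_events(tr) == []

    def test_single_step_detected_once(self):
        t = np.linspace(0, 1, 200)
        E = 0.5 + 0.5 * t
        E[t >= 0.6] += 10.0
        tr = make_trace(t, E, -100 * t)
        events = metrics.detect_snap_events(tr)
        assert len(events) == 1
        assert events[0].time == pytest.approx(0.6, abs=2 / 200)
        assert events[0].direction == "inversion"
        assert events[0].energy_jump == pytest.approx(10.0, rel=0.05)

    def test_two_jump_pattern_ordered(self):
        t = np.linspace(0, 2, 400)
        E = 0.2 + 0.3 * t
        E[t >= 0.5] += 5.0
        E[t >= 1.5] -= 4.0
        p = np.where(t < 1.0, -100 * t, -100 + 150 * (t - 1.0))
        tr = make_trace(t, E, p)
        events = metrics.detect_snap_events(tr)
        assert [ev.ordinal for ev in events] == [1, 2]
        assert events[0].time < events[1].time
        assert events[0].direction == "inversion"
        assert events[1].direction == "recovery"
        # event pressure is read from the trace
        assert events[0].pressure == pytest.approx(
            np.interp(events[0].time, t, p), abs=2.0)

    def test_threshold_monotonicity(self):
        t = np.linspace(0, 1, 300)
        rng = np.random.default_rng(4)
        E = np.cumsum(np.abs(rng.standard_normal(300))) / 10
        E[100:] += 3.0
        E[200:] += 1.0
        tr = make_trace(t, E, -100 * t)
        counts = [len(metrics.detect_snap_events(tr, rel_threshold=r))
                  for r in (0.02, 0.05, 0.10, 0.30, 0.90)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_idempotence(self):
        t = np.linspace(0, 1, 200)
        E = np.where(t > 0.4, 8.0, 1.0)
        tr = make_trace(t, E, -10 * t)
        e1 = metrics.detect_snap_events(tr)
        e2 = metrics.detect_snap_events(tr)
        assert e1 == e2

    def test_short_trace_rejected(self):
        tr = make_trace([0.0, 1.0], [0.0, 1.0], [0.0, -1.0])
        with pytest.raises(ValueError):
            metrics.detect_snap_events(tr)


class TestEventPressures:
    def test_inversion_pressure_first_event(self):
        evs = [metrics.SnapEvent(2.0, -50.0, 1.0, "inversion", 1),
               metrics.SnapEvent(3.0, -80.0, 1.0, "inversion", 2)]
        assert metrics.inversion_pressure(evs) == -50.0

    def test_no_inversion_sentinel(self):
        assert np.isnan(metrics.inversion_pressure([]))

    def test_recovery_excess(self):
        evs = [metrics.SnapEvent(9.0, 40.0, -1.0, "recovery", 1)]
        assert metrics.recovery_excess_pressure(evs) == pytest.approx(31.0)
        evs = [metrics.SnapEvent(9.0, 9.0, -1.0, "recovery", 1)]
        assert metrics.recovery_excess_pressure(evs) == pytest.approx(0.0)

    def test_no_recovery_sentinel(self):
        evs = [metrics.SnapEvent(2.0, -50.0, 1.0, "inversion", 1)]
        assert np.isnan(metrics.recovery_excess_pressure(evs))


class TestOrificeFrame:
    def _ring_mesh(self, ring_pts, extra=None):
        pts = [ring_pts]
        if extra is not None:
            pts.append(extra)
        nodes = np.vstack(pts)
        return geo.VolumeMesh(nodes, np.empty((0, 4), np.int64),
                              np.empty((0, 3), np.int64),
                              np.arange(len(ring_pts)))

    def test_planar_ring_exact(self):
        th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        ring = np.column_stack([5 * np.cos(th), 5 * np.sin(th),
                                np.full(24, 2.0)])
        interior = np.array([[0.0, 0.0, -10.0]])
        mesh = self._ring_mesh(ring, interior)
        point, normal = metrics.orifice_frame(mesh)
        assert abs(abs(normal[2]) - 1.0) < 1e-12
        assert point[2] == pytest.approx(2.0)
        # oriented away from the interior (centroid below the plane)
        assert normal[2] > 0

    def test_noisy_ring_within_noise(self):
        rng = np.random.default_rng(0)
        th = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        ring = np.column_stack([5 * np.cos(th), 5 * np.sin(th),
                                0.01 * rng.standard_normal(48)])
        mesh = self._ring_mesh(ring, np.array([[0, 0, -8.0]]))
        point, normal = metrics.orifice_frame(mesh)
        assert abs(point[2]) < 0.01
        assert abs(abs(normal[2]) - 1) < 1e-3

    def test_collinear_rejected(self):
        ring = np.column_stack([np.linspace(0, 1, 5), np.zeros(5),
                                np.zeros(5)])
        with pytest.raises(ValueError):
            metrics.orifice_frame(self._ring_mesh(ring))


class TestProtrusion:
    def test_reference_equals_minus_depth(self, coarse_wing):
        frame = metrics.orifice_frame(coarse_wing)
        tip = metrics.tip_node_set(coarse_wing, frame)
        p0 = metrics.tip_protrusion(coarse_wing.nodes[tip].mean(axis=0),
                                    frame)
        point, normal = frame
        depth = -((coarse_wing.nodes - point) @ normal).min()
        assert p0 < 0
        assert abs(p0) == pytest.approx(depth, rel=0.15)

    def test_mirror_flips_sign(self, coarse_wing):
        frame = metrics.orifice_frame(coarse_wing)
        point, normal = frame
        tip = metrics.tip_node_set(coarse_wing, frame)
        c = coarse_wing.nodes[tip].mean(axis=0)
        mirrored = c - 2 * ((c - point) @ normal) * normal
        assert metrics.tip_protrusion(mirrored, frame) == pytest.approx(
            -metrics.tip_protrusion(c, frame), rel=1e-9)


class TestClassification:
    def test_no_events_anatomical(self):
        t = np.linspace(0, 1, 50)
        prots = np.full(50, -20.0)
        labels = metrics.classify_configuration(t, prots, [], -20.0)
        assert [L.label for L in labels] == ["anatomical"]

    def test_single_event_initial_equals_final(self):
        t = np.linspace(0, 1, 100)
        prots = np.where(t < 0.5, -20.0, 5.0)
        ev = [metrics.SnapEvent(0.5, -110.0, 50.0, "inversion", 1)]
        labels = metrics.classify_configuration(t, prots, ev, -20.0)
        names = [L.label for L in labels]
        assert names == ["anatomical", "initial_snapped_through",
                         "final_snapped_through"]
        assert labels[1].time == labels[2].time

    def test_cap_cycle_sequence(self, cap_cycle):
        res = cap_cycle["result"]
        frame = cap_cycle["frame"]
        tr = res.trace
        prots = np.array([metrics.tip_protrusion(c, frame)
                          for c in tr.tip_centroid])
        events = metrics.detect_snap_events(tr)
        labels = metrics.classify_configuration(tr.time, prots, events,
                                                prots[0])
        names = [L.label for L in labels]
        assert names[0] == "anatomical"
        assert "initial_snapped_through" in names
        assert "recovered" in names
        # inverted configurations protrude toward the atrium (positive side)
        final = [L for L in labels if L.label == "final_snapped_through"][0]
        assert final.tip_protrusion > 0

    def test_rotation_invariance(self, cap_cycle):
        # rotating mesh + trajectory rigidly leaves the labels unchanged
        res = cap_cycle["result"]
        mesh = cap_cycle["mesh"]
        c, s = np.cos(0.7), np.sin(0.7)
        R = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
        rot = geo.VolumeMesh(mesh.nodes @ R.T, mesh.tets, mesh.inner_facets,
                             mesh.orifice_ring)
        frame_r = metrics.orifice_frame(rot)
        tr = res.trace
        prots = np.array([metrics.tip_protrusion(c_ @ R.T, frame_r)
                          for c_ in tr.tip_centroid])
        events = metrics.detect_snap_events(tr)
        labels_r = metrics.classify_configuration(tr.time, prots, events,
                                                  prots[0])
        frame0 = cap_cycle["frame"]
        prots0 = np.array([metrics.tip_protrusion(c_, frame0)
                           for c_ in tr.tip_centroid])
        labels0 = metrics.classify_configuration(tr.time, prots0, events,
                                                 prots0[0])
        assert [L.label for L in labels_r] == [L.label for L in labels0]
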