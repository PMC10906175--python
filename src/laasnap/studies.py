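"""Canned study runs: benchmark cycles and the mesh-convergence protocol.

These bundle geometry, protocol and solver settings for the package's
standard numerical experiments, so the analysis drivers, the test suite and
the acceptance script all execute exactly the same computation.  Problem
sizes are desk-scale: coarse meshes, mass scaling and time compression, with
validity policed by the kinetic-energy QC and the energy audit.
"""

from __future__ import annotations

import numpy as np

from . import fem, geometry as geo, metrics, ogden
from . import protocol as proto

__all__ = ["cap_snap_through", "tube_eversion", "mesh_convergence",
           "inversion_cycle"]

#: cap benchmark: pressures scaled to the cap's critical loads, time
#: compressed for the explicit solver
CAP_PRESSURE_SCALE = 0.15
CAP_TIME_SCALE = 0.02

#: suction level (mmHg) at which the convergence study reads the peak
#: trabecular cable force (cables engaged, pre-chaotic regime)
CONVERGENCE_LEVEL_MMHG = -90.0


def cap_snap_through(seed: int = 0) -> dict:
    """Clamped spherical cap through the scaled four-stage protocol.

    The canonical bistable shell: snaps through under suction (stage 1),
    stays inverted through the plateau, snaps back under the stage-4
    overpressure.
    """
    cap = geo.make_benchmark("spherical_cap", radius=10.0, thickness=1.5,
                             half_angle=50.0, edge=1.5)
    frame = metrics.orifice_frame(cap)
    tip = metrics.tip_node_set(cap, frame)
    protocol = proto.standard_protocol().scaled(pressure=CAP_PRESSURE_SCALE,
                                                time=CAP_TIME_SCALE)
    cfg = fem.ExplicitConfig(mass_scaling=16.0, mass_damping=100.0,
                             output_interval=1e-3)
    res = fem.run_protocol(cap, ogden.table1(), protocol, cfg,
                           track_nodes=tip)
    return {"mesh": cap, "frame": frame, "protocol": protocol,
            "result": res, "pressure_scale": CAP_PRESSURE_SCALE}


def tube_eversion(seed: int = 0) -> dict:
    """Closed tube sucked to -150 mmHg and released: full eversion with
    self-contact, settling in the everted equilibrium at zero load."""
    tube = geo.make_benchmark("closed_tube", radius=5.0, thickness=1.0,
                              length=25.0, edge=1.8)
    frame = metrics.orifice_frame(tube)
    tip = metrics.tip_node_set(tube, frame)
    protocol = proto.PressureProtocol(times=(0.0, 0.4, 0.5, 0.65),
                                      pressures=(0.0, -150.0, 0.0, 0.0),
                                      stage_bounds=(0.0, 0.4, 0.5, 0.65))
    cfg = fem.ExplicitConfig(mass_scaling=16.0, mass_damping=300.0,
                             dt_safety=0.5, output_interval=2e-3,
                             contact_enabled=True, contact_offset=0.6,
                             contact_penalty=0.3)
    res = fem.run_protocol(tube, ogden.table1(), protocol, cfg,
                           track_nodes=tip)
    return {"mesh": tube, "frame": frame, "protocol": protocol,
            "result": res, "length": 25.0}


def mesh_convergence(seed: int = 0, base_edge: float = 2.8,
                     level_mmhg: float = CONVERGENCE_LEVEL_MMHG):
    """Three-mesh (~20% element increments) suction-ramp study on the
    trabeculated chicken-wing reference geometry.

    Returns (rows, rel_diff_mid_pct, rel_diff_finer_two_pct) where each row
    holds the element count and the peak trabecular cable force reached by
    ``level_mmhg``.

    Convergence is a property of one fixed geometry (the canonical
    chicken-wing reference, ``seed=0``): at other seeds the seeded trabecula
    placement can land cables in marginally engaged positions where the
    tension-only force at a fixed suction is a knife-edge quantity rather
    than a convergent one (see the methods note).  ``seed`` is exposed for
    sensitivity exploration.
    """
    params = geo.preset_params("chicken_wing", seed=seed,
                               target_edge_length=base_edge, n_layers=1)
    series = geo.mesh_series(params, n=3, increment=0.20)
    protocol = proto.PressureProtocol(times=(0.0, 0.25),
                                      pressures=(9.0, -120.0),
                                      stage_bounds=(0.0, 0.25))
    cfg = fem.ExplicitConfig(mass_scaling=16.0, mass_damping=300.0,
                             output_interval=2e-3)
    mat = ogden.table1()
    rows = []
    for mesh in series:
        res = fem.run_protocol(mesh, mat, protocol, cfg)
        tr = res.trace
        peak = float(tr.max_cable_force[tr.pressure >= level_mmhg].max())
        rows.append({"n_elements": mesh.n_elements,
                     "peak_cable_force_N": peak, "aborted": res.aborted})
    d_mid = abs(rows[1]["peak_cable_force_N"]
                / rows[0]["peak_cable_force_N"] - 1.0) * 100.0
    d_fine = abs(rows[2]["peak_cable_force_N"]
                 / rows[1]["peak_cable_force_N"] - 1.0) * 100.0
    return rows, d_mid, d_fine


def inversion_cycle(seed: int = 0, morphology: str = "chicken_wing",
                    edge: float = 2.8, time_scale: float = 0.03,
                    hold_s: float = 0.45) -> dict:
    """Full inversion/recovery cycle of a synthetic appendage at the study's
    printed protocol pressures, time-compressed with a stage-4 hold long
    enough for the recovery wave to complete."""
    mesh = geo.build_appendage(geo.preset_params(
        morphology, seed=seed, target_edge_length=edge, n_layers=1))
    frame = metrics.orifice_frame(mesh)
    tip = metrics.tip_node_set(mesh, frame)
    base = proto.standard_protocol().scaled(time=time_scale)
    protocol = proto.PressureProtocol(
        times=base.times + (base.t_end + hold_s,),
        pressures=base.pressures + (base.pressures[-1],),
        stage_bounds=base.stage_bounds + (base.t_end + hold_s,))
    cfg = fem.ExplicitConfig(mass_scaling=16.0, mass_damping=300.0,
                             dt_safety=0.5, output_interval=1e-3,
                             contact_enabled=True, contact_offset=0.6,
                             contact_penalty=0.3)
    res = fem.run_protocol(mesh, ogden.table1(), protocol, cfg,
                           track_nodes=tip)
    return {"mesh": mesh, "frame": frame, "protocol": protocol,
            "result": res, "time_scale": time_scale}
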