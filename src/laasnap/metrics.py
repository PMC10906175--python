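"""Snap-through event detection and configuration classification.

Inversion proceeds by eversion punctuated by snap-through events: sudden
jumps between equilibrium branches that show up as abrupt changes in the
strain-energy trace.  The detector below makes that visual criterion
operational: after median smoothing, a sample-to-sample energy change larger
than a relative threshold times the running energy maximum is an event;
its direction comes from the sign of the pressure ramp at that time
(falling pressure → inversion, rising → recovery).

Configurations follow the study taxonomy: *anatomical* before any event,
*initial snapped-through* at the first inversion event, *final
snapped-through* after the last inversion-phase event, *recovered* when a
recovery event returns the tip protrusion to the reference side within
tolerance (a pressurized, slightly inflated final state still counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from .fem import EnergyTrace
from .geometry import VolumeMesh

__all__ = [
    "SnapEvent", "ConfigurationLabel", "detect_snap_events",
    "inversion_pressure", "recovery_excess_pressure", "orifice_frame",
    "tip_node_set", "tip_protrusion", "classify_configuration",
]


@dataclass(frozen=True)
class SnapEvent:
    time: float
    pressure: float          # mmHg, read from the trace at the event
    energy_jump: float       # mJ, signed change across the event
    direction: str           # "inversion" | "recovery"
    ordinal: int


@dataclass(frozen=True)
class ConfigurationLabel:
    label: str               # anatomical | initial_snapped_through |
    #                          final_snapped_through | recovered | intermediate
    tip_protrusion: float    # mm
    time: float
    partial_invagination: bool = False


def detect_snap_events(trace: EnergyTrace, rel_threshold: float = 0.05,
                       window: int = 5, min_rel_energy: float = 0.02,
                       min_abs_energy: float = 1e-9) -> list[SnapEvent]:
    """Detect abrupt strain-energy changes.

    A sample-to-sample change of the median-filtered energy exceeding
    ``rel_threshold`` x (running max energy) is an event; adjacent
    detections merge into one, timed at the largest single-sample change.
    ``min_rel_energy`` floors the running max at that fraction of the
    trace-wide maximum, so numerical flutter before any load has built up
    does not register; a trace that never exceeds ``min_abs_energy`` (mJ) is
    treated as unloaded and yields no events.
    """
    E = np.asarray(trace.strain, float)
    if len(E) < 3:
        raise ValueError("trace too short for event detection")
    if float(np.max(np.abs(E))) <= min_abs_energy:
        return []
    if window > 1:
        w = window + 1 - window % 2  # odd
        Es = medfilt(E, min(w, len(E) - (1 - len(E) % 2)))
    else:
        Es = E
    run_max = np.maximum.accumulate(np.abs(Es))
    floor = min_rel_energy * float(np.max(np.abs(Es)))
    dE = np.diff(Es)
    thresh = rel_threshold * np.maximum(run_max[:-1], floor)
    # an event must also be abrupt: a several-fold outlier against the
    # trace-wide median increment (most samples are slow loading), so
    # smooth-but-fast energy growth is not flagged
    typical = float(np.median(np.abs(dE)))
    hits = (np.abs(dE) > thresh) & (np.abs(dE) > 4.0 * typical)

    # pressure slope (smoothed) for direction labels
    p = np.asarray(trace.pressure, float)
    t = np.asarray(trace.time, float)

    events: list[SnapEvent] = []
    i = 0
    while i < len(hits):
        if not hits[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(hits) and hits[j + 1]:
            j += 1
        k = i + int(np.argmax(np.abs(dE[i:j + 1])))
        jump = float(Es[j + 1] - Es[i])
        # local pressure slope over the merged window
        i0, i1 = max(i - 1, 0), min(j + 2, len(p) - 1)
        dp = p[i1] - p[i0]
        direction = "inversion" if dp < 0 else "recovery"
        events.append(SnapEvent(
            time=float(t[k + 1]), pressure=float(p[k + 1]),
            energy_jump=jump, direction=direction, ordinal=len(events) + 1))
        i = j + 1
    return events


_NO_EVENT = float("nan")


def inversion_pressure(events: list[SnapEvent]) -> float:
    """Pressure (mmHg) at the first inversion event; NaN if none detected."""
    for ev in events:
        if ev.direction == "inversion":
            return ev.pressure
    return _NO_EVENT


def recovery_excess_pressure(events: list[SnapEvent],
                             p_physiological: float = 9.0) -> float:
    """Pressure excess over the physiological value at the final recovery
    event; NaN if no recovery event was detected."""
    rec = [ev for ev in events if ev.direction == "recovery"]
    if not rec:
        return _NO_EVENT
    return rec[-1].pressure - p_physiological


def orifice_frame(mesh: VolumeMesh) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through the orifice ring.

    Returns (point on plane, unit normal); the normal points away from the
    appendage interior (away from the mesh centroid), i.e. toward the atrium.
    """
    ring = mesh.nodes[mesh.orifice_ring]
    if len(ring) < 3:
        raise ValueError("orifice ring needs at least 3 nodes")
    c = ring.mean(axis=0)
    _, s, vt = np.linalg.svd(ring - c)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise ValueError("orifice ring nodes are collinear")
    n = vt[2]
    if n @ (mesh.nodes.mean(axis=0) - c) > 0:
        n = -n
    return c, n


def tip_node_set(mesh: VolumeMesh, frame=None, band: float = 0.95
                 ) -> np.ndarray:
    """Distal-tip node set: nodes beyond the ``band`` quantile of reference
    distance from the orifice plane (averaging a band is robust to
    single-node noise)."""
    if frame is None:
        frame = orifice_frame(mesh)
    point, normal = frame
    d = (mesh.nodes - point) @ normal      # signed, negative into appendage
    depth = -d
    cut = np.quantile(depth, band)
    return np.where(depth >= cut)[0]


def tip_protrusion(x_tip_centroid: np.ndarray, frame) -> float:
    """Signed distance of the current tip centroid to the orifice plane,
    positive toward the atrium."""
    point, normal = frame
    return float((np.asarray(x_tip_centroid) - point) @ normal)


def classify_configuration(times: np.ndarray, protrusion: np.ndarray,
                           events: list[SnapEvent],
                           reference_protrusion: float,
                           height: float | None = None,
                           tol: float = 0.10) -> list[ConfigurationLabel]:
    """Label the trajectory at event times and endpoints.

    ``protrusion`` is the tip protrusion sampled at ``times``;
    ``reference_protrusion`` its anatomical value (negative: tip inside the
    appendage).  ``height`` defaults to |reference_protrusion|.  *recovered*
    requires a recovery event after which the protrusion returns to the
    reference side within ``tol`` x height (or deeper — a slightly inflated
    recovered state still counts).
    """
    times = np.asarray(times, float)
    protrusion = np.asarray(protrusion, float)
    if len(times) != len(protrusion):
        raise ValueError("times and protrusion must align")
    if height is None:
        height = abs(reference_protrusion)
    labels: list[ConfigurationLabel] = []

    def prot_at(tq: float) -> float:
        return float(np.interp(tq, times, protrusion))

    labels.append(ConfigurationLabel("anatomical", protrusion[0],
                                     float(times[0])))
    inv = [ev for ev in events if ev.direction == "inversion"]
    rec = [ev for ev in events if ev.direction == "recovery"]
    if inv:
        p1 = prot_at(inv[0].time)
        labels.append(ConfigurationLabel("initial_snapped_through", p1,
                                         inv[0].time))
        pf = prot_at(inv[-1].time)
        labels.append(ConfigurationLabel(
            "final_snapped_through", pf, inv[-1].time,
            partial_invagination=pf < 0.0))
    for k, ev in enumerate(rec):
        pr = prot_at(ev.time)
        if k < len(rec) - 1:
            # unloading events before the final recovery snap
            labels.append(ConfigurationLabel("intermediate", pr, ev.time))
            continue
        after = protrusion[times >= ev.time]
        recovered = np.any(after <= reference_protrusion + tol * height)
        labels.append(ConfigurationLabel(
            "recovered" if recovered else "intermediate", pr, ev.time))
    return labels
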