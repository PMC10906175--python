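"""Shared fixtures.

Heavy solver runs (cap hysteresis cycle, Lamé shell relaxation) are
session-scoped so that several tests can interrogate one trajectory.
"""

import numpy as np
import pytest

from laasnap import geometry as geo, ogden


@pytest.fixture(scope="session")
def mat():
    return ogden.table1()


@pytest.fixture(scope="session")
def single_tet():
    nodes = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                      [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    tets = np.array([[0, 1, 2, 3]])
    return geo.VolumeMesh(nodes, tets, np.empty((0, 3), np.int64),
                          np.empty(0, np.int64))


@pytest.fixture(scope="session")
def small_shell():
    """Coarse closed spherical shell for force-consistency checks."""
    return geo.sphere_shell(6.0, 1.5, 2.5)


@pytest.fixture(scope="session")
def coarse_wing():
    """Desk-scale chicken-wing appendage (single wall layer)."""
    return geo.build_appendage(geo.preset_params(
        "chicken_wing", target_edge_length=2.8, n_layers=1))


@pytest.fixture(scope="session")
def cap_cycle():
    """Spherical-cap benchmark driven through the scaled four-stage
    protocol: the canonical snap-through hysteresis trajectory."""
    from laasnap import studies
    run = studies.cap_snap_through()
    assert not run["result"].aborted, run["result"].abort_reason
    return run
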