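"""Shared fixtures: coarse meshes and solved systems reused across the suite.

All geometry/flow/transport objects are built once per session at reduced
resolution so the full suite stays fast; physics tests that need resolution
state it locally.
"""

import numpy as np
import pytest

import isletsim as isl
from isletsim.transport import TransportSystem

COARSE = 300e-6   # lumen element size for fast test meshes [m]


@pytest.fixture(scope="session")
def two_islet_mesh():
    return isl.mesh_geometry(isl.build_chamber(isl.default_two_islet_chamber()),
                             resolution=COARSE, seed=0)


@pytest.fixture(scope="session")
def two_islet_system(two_islet_mesh):
    vel = isl.solve_steady_flow(two_islet_mesh)
    return TransportSystem(two_islet_mesh, vel)


@pytest.fixture(scope="session")
def encapsulated_system():
    mesh = isl.mesh_geometry(
        isl.build_chamber(isl.default_two_islet_chamber(encapsulated=True)),
        resolution=COARSE, seed=0)
    return TransportSystem(mesh, isl.solve_steady_flow(mesh))


@pytest.fixture(scope="session")
def empty_chamber_mesh():
    return isl.mesh_geometry(isl.build_chamber(isl.ChamberSpec()),
                             resolution=COARSE, seed=0)


@pytest.fixture(scope="session")
def single_islet_mesh():
    spec = isl.ChamberSpec(islets=(isl.IsletSpec((6e-3, 2e-3), 150e-6),))
    return isl.mesh_geometry(isl.build_chamber(spec), resolution=COARSE, seed=0)
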