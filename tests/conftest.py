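import numpy as np
import pytest

from perfusim import (
    BoundaryPatch,
    CellRuleParams,
    PatchKind,
    StructuredGrid,
    solve_steady_flow,
)


@pytest.fixture(scope="session")
def open_box_grid():
    """Closed 3D box of free fluid, 1 mm x 1 mm x 0.2 mm at 40x40x8."""
    g = StructuredGrid(40, 40, 8, 2.5e-5, 2.5e-5, 2.5e-5, origin=np.zeros(3))
    g.attach_patches([])
    return g


@pytest.fixture(scope="session")
def channel_flow():
    """Plane-channel Stokes solution used by several transport tests."""
    H, L = 2e-4, 1e-3
    nx, ny = 60, 15
    g = StructuredGrid(nx, ny, 1, L / nx, H / ny, 1e-4, origin=np.zeros(3))
    g.attach_patches([
        BoundaryPatch("inlet", "-x", PatchKind.VELOCITY_INLET,
                      inlet_velocity=0.001, inlet_concentration=0.21),
        BoundaryPatch("outlet", "+x", PatchKind.PRESSURE_OUTLET),
    ])
    return g, solve_steady_flow(g)


@pytest.fixture()
def params():
    return CellRuleParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
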