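"""Scenario presets and synthetic test fixtures.

The bioreactor presets bind the published device parameters: two box
bioreactors (geometry A: corner inlet / corner outlet; geometry B:
corner inlet, two full outlet faces) perfused at two inlet speeds, and a
planar two-well chemotaxis chamber.  Inlet speeds are stored in SI; the
device values 0.001 and 0.01 are per-hour figures (see the methods note
on the unit system), i.e. 2.78e-7 and 2.78e-6 m/s.

Bioreactor runs start with a deoxygenated scaffold fed by oxygenated
medium (0.21 mol/m^3) at the inlet, which is what makes hypoxia-driven
chemotaxis and apoptosis possible at all; the chamber preset starts with
the attractant loaded in the outer well only and no flow.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cell_agents import Agent, CellRuleParams, random_unit_vector
from .coupling_driver import SimulationConfig
from .errors import ConfigurationError
from .flow_solver import FlowState, zero_flow
from .grid_geometry import BoundaryPatch, PatchKind, StructuredGrid
from .species_transport import SpeciesProperties, make_field

__all__ = ["scenario", "SCENARIOS", "make_fixture"]

#: device inlet speeds: printed figures are per-hour values
INLET_LOW = 0.001 / 3600.0   # m/s
INLET_HIGH = 0.01 / 3600.0   # m/s

REDUCED_RESOLUTION = (40, 40, 8)


def _bioreactor(name, preset, n_cells, inlet, duration_h) -> SimulationConfig:
    return SimulationConfig(
        name=name,
        preset=preset,
        resolution=REDUCED_RESOLUTION,
        species=SpeciesProperties(
            name="oxygen",
            diffusivity=1e-5 / 3600.0,
            inlet_concentration=0.21,
            initial_concentration=0.21,
        ),
        cells=CellRuleParams(),
        n_cells=n_cells,
        inlet_velocity=inlet,
        duration_hours=duration_h,
    )


def _insall(name: str, with_attractant: bool) -> SimulationConfig:
    c0 = 1.0  # outer-well loading, arbitrary concentration units
    return SimulationConfig(
        name=name,
        preset="INSALL",
        resolution=(45, 20, 1),
        species=SpeciesProperties(
            name="fbs",
            diffusivity=8.705e-11,
            inlet_concentration=0.0,
            initial_concentration=c0 if with_attractant else 0.0,
        ),
        cells=CellRuleParams.mv3(outer_well_concentration=c0),
        n_cells=20,
        placement="bridge",
        initial_field="outer_well",
        solve_flow=False,
        duration_hours=25.0,
    )


SCENARIOS = {
    "CASE1": lambda: _bioreactor("CASE1", "GEOMETRY_A", 100, INLET_LOW, 96.0),
    "CASE2": lambda: _bioreactor("CASE2", "GEOMETRY_A", 100, INLET_HIGH, 96.0),
    "CASE3": lambda: _bioreactor("CASE3", "GEOMETRY_B", 5, INLET_LOW, 144.0),
    "CASE4": lambda: _bioreactor("CASE4", "GEOMETRY_B", 5, INLET_HIGH, 144.0),
    "INSALL": lambda: _insall("INSALL", with_attractant=True),
    "INSALL_CONTROL": lambda: _insall("INSALL_CONTROL", with_attractant=False),
    "TEST2D": lambda: dataclasses.replace(
        _bioreactor("TEST2D", "GEOMETRY_A", 10, INLET_LOW, 12.0),
        resolution=(20, 20, 1),
    ),
}


def scenario(name: str, **overrides) -> SimulationConfig:
    """Build a named scenario preset, optionally overriding fields."""
    try:
        cfg = SCENARIOS[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        ) from None
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# synthetic fixtures for tests and the acceptance checks
# ---------------------------------------------------------------------------

def make_fixture(kind: str, params: dict | None = None, rng=None):
    """Deterministic synthetic fixtures.

    Kinds:
      ``linear_field``  grid + scalar field ``c0 + slope * x``
      ``sealed_single_cv``  one closed CV with one resident cell
      ``agent_cloud``  n non-overlapping agents in a box
      ``plane_channel``  2D channel grid with inlet/outlet patches
      ``uniform_flow``  grid + FlowState with a uniform x-directed flux
    """
    params = dict(params or {})
    if rng is None:
        rng = np.random.default_rng(params.pop("seed", 0))
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    if kind == "linear_field":
        n = params.get("resolution", (50, 20, 4))
        L = params.get("length", 1e-3)
        c0 = params.get("c0", 1.0)
        slope = params.get("slope", 100.0)
        grid = StructuredGrid(
            n[0], n[1], n[2], L / n[0],
            params.get("width", 1e-3) / n[1],
            params.get("depth", 2e-4) / n[2],
            origin=np.zeros(3),
        )
        grid.attach_patches([])
        x = grid.centers(0)
        phi = np.broadcast_to(
            (c0 + slope * x)[:, None, None], grid.shape
        ).copy()
        species = SpeciesProperties(
            name=params.get("name", "oxygen"),
            diffusivity=params.get("diffusivity", 1e-5 / 3600.0),
            inlet_concentration=0.0,
            initial_concentration=c0,
        )
        field = make_field(grid, species, phi=phi)
        return {"grid": grid, "field": field, "species": species,
                "c0": c0, "slope": slope}

    if kind == "sealed_single_cv":
        h = params.get("edge", 1e-4)
        c0 = params.get("c0", 20.0)
        grid = StructuredGrid(1, 1, 1, h, h, h, origin=np.zeros(3))
        grid.attach_patches([])
        species = SpeciesProperties(initial_concentration=c0)
        field = make_field(grid, species)
        cell = Agent(
            id=0, position=grid.cell_center((0, 0, 0)),
            direction=np.array([1.0, 0.0, 0.0]), division_class=18.0,
        )
        return {"grid": grid, "field": field, "species": species, "agent": cell}

    if kind == "agent_cloud":
        n = params.get("n", 50)
        box = params.get("box", (1e-3, 1e-3, 2e-4))
        r = params.get("radius", 10e-6)
        pos = []
        while len(pos) < n:
            p = rng.uniform([r] * 3, np.array(box) - r)
            if pos and np.min(np.linalg.norm(np.array(pos) - p, axis=1)) < 2 * r:
                continue
            pos.append(p)
        agents = [
            Agent(id=i, position=p, direction=random_unit_vector(rng),
                  division_class=18.0, radius=r)
            for i, p in enumerate(pos)
        ]
        return {"agents": agents, "box": np.array(box)}

    if kind == "plane_channel":
        n = params.get("resolution", (60, 15, 1))
        H = params.get("height", 2e-4)
        L = params.get("length", 1e-3)
        u = params.get("inlet_velocity", 0.001)
        grid = StructuredGrid(n[0], n[1], n[2], L / n[0], H / n[1],
                              params.get("depth", 1e-4), origin=np.zeros(3))
        grid.attach_patches([
            BoundaryPatch("inlet", "-x", PatchKind.VELOCITY_INLET,
                          inlet_velocity=u, inlet_concentration=0.21),
            BoundaryPatch("outlet", "+x", PatchKind.PRESSURE_OUTLET),
        ])
        return {"grid": grid, "inlet_velocity": u}

    if kind == "uniform_flow":
        n = params.get("resolution", (50, 1, 1))
        L = params.get("length", 1e-3)
        u = params.get("velocity", 1e-5)
        cin = params.get("inlet_concentration", 1.0)
        grid = StructuredGrid(n[0], n[1], n[2], L / n[0],
                              params.get("width", 1e-4),
                              params.get("depth", 1e-4), origin=np.zeros(3))
        grid.attach_patches([
            BoundaryPatch("inlet", "-x", PatchKind.VELOCITY_INLET,
                          inlet_velocity=u, inlet_concentration=cin),
            BoundaryPatch("outlet", "+x", PatchKind.PRESSURE_OUTLET),
        ])
        flow = zero_flow(grid)
        flow.fluxes[0][:] = u * grid.face_area(0)
        return {"grid": grid, "flow": flow, "velocity": u}

    raise ConfigurationError(f"unknown fixture kind {kind!r}")
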