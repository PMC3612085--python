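"""Orchestration of the transport <-> agent coupling loop.

A scenario runs in fixed 15-minute coupling cycles.  The steady flow
field is solved once (cells are species sinks only, they do not alter
the scaffold), then each cycle: (1) live agents deposit their linearized
consumption into their CVs, (2) the scalar field takes one implicit
transport step, (3) every agent samples its local concentration and
gradient and updates hypoxia clocks, motion, contacts and division.
Agents are processed in id order with a dedicated RNG substream per
(cycle, agent), so runs are bit-for-bit reproducible per seed while
approximating asynchronous behavior.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_agents import (
    Agent,
    AgentState,
    CellRuleParams,
    attempt_division,
    random_unit_vector,
    resolve_contacts,
    sample_division_class,
    step_motility,
    update_hypoxia,
    _wants_chemotaxis,
)
from .errors import ConfigurationError, SolverError
from .flow_solver import FluidProperties, FlowState, solve_steady_flow, zero_flow
from .grid_geometry import CVKind, PatchKind, StructuredGrid, build_grid
from .species_transport import (
    ScalarFieldState,
    SpeciesProperties,
    TransportOperator,
    assemble_sink_field,
    make_field,
    mass_budget,
    _fill_blocked,
    _gradient_arrays,
    _trilinear,
)

__all__ = [
    "SimulationConfig",
    "CycleRecord",
    "SimulationResult",
    "run_simulation",
    "run_insall_validation",
]

HOUR = 3600.0


@dataclass
class SimulationConfig:
    """Complete scenario description; serializable to YAML (see io_utils)."""

    name: str = "custom"
    preset: str = "GEOMETRY_A"
    resolution: tuple = (40, 40, 8)
    geometry_overrides: dict = field(default_factory=dict)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    species: SpeciesProperties = field(default_factory=SpeciesProperties)
    cells: CellRuleParams = field(default_factory=CellRuleParams)
    n_cells: int = 100
    placement: str = "uniform"          # "uniform" | "bridge"
    initial_field: str = "uniform"      # "uniform" | "outer_well"
    inlet_velocity: float | None = None  # m/s; None keeps the preset default
    solve_flow: bool = True
    cycle_hours: float = 0.25
    duration_hours: float = 96.0
    seed: int = 0
    sink_cutoff_fraction: float = 0.01  # of the reference concentration
    transport_substeps: int = 1
    scheme: str = "tvd"
    flow_tolerance: float = 1e-8
    snapshot_every: int = 0             # cycles between VTK snapshots (0 = off)

    def __post_init__(self):
        if self.cycle_hours <= 0:
            raise ConfigurationError("cycle_hours must be > 0")
        n = self.duration_hours / self.cycle_hours
        if self.duration_hours <= 0 or abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "duration_hours must be a positive multiple of cycle_hours"
            )
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")

    @property
    def n_cycles(self) -> int:
        return int(round(self.duration_hours / self.cycle_hours))

    @property
    def sink_cutoff(self) -> float:
        ref = max(self.species.inlet_concentration, self.species.initial_concentration)
        return self.sink_cutoff_fraction * ref

    def build_grid(self) -> StructuredGrid:
        overrides = dict(self.geometry_overrides)
        if self.inlet_velocity is not None and self.preset in ("GEOMETRY_A", "GEOMETRY_B"):
            overrides.setdefault("inlet_velocity", self.inlet_velocity)
            overrides.setdefault("inlet_concentration", self.species.inlet_concentration)
        return build_grid(self.preset, self.resolution, **overrides)


@dataclass
class CycleRecord:
    cycle: int
    time_h: float
    n_live: int
    n_rw: int
    n_chemo: int
    n_arrested: int
    n_dead: int
    n_flagged: int
    births: int
    deaths: int
    total_mass: float
    min_phi: float
    mean_phi: float
    ledger_closure: float


@dataclass
class SimulationResult:
    config: SimulationConfig
    grid: StructuredGrid
    flow: FlowState
    field: ScalarFieldState
    agents: list
    records: list
    initial_positions: np.ndarray
    snapshots: list = field(default_factory=list)  # (cycle, phi copy)

    @property
    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])

    @property
    def live_agents(self) -> list:
        return [a for a in self.agents if a.is_live]


def _bond_counts(live_agents, params) -> np.ndarray:
    """Bonded-neighbour counts for all live agents in one KD-tree pass."""
    if not live_agents:
        return np.zeros(0, dtype=int)
    from scipy.spatial import cKDTree

    pos = np.array([a.position for a in live_agents])
    r = params.radius
    tree = cKDTree(pos)
    counts = tree.query_ball_point(
        pos, 2.0 * r * (1.0 + params.bond_tolerance), return_length=True
    )
    return np.asarray(counts, dtype=int) - 1  # exclude self


def _agent_rng(seed: int, cycle: int, agent_id: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(cycle, agent_id))
    )


def _initial_phi(config: SimulationConfig, grid: StructuredGrid) -> np.ndarray:
    if config.initial_field == "uniform":
        return np.full(grid.shape, config.species.initial_concentration)
    if config.initial_field == "outer_well":
        xw = grid.meta.get("outer_well_length")
        if xw is None:
            raise ConfigurationError("outer_well initial field needs the INSALL preset")
        xc = grid.centers(0)
        phi = np.zeros(grid.shape)
        phi[xc < xw, :, :] = config.species.initial_concentration
        return phi
    raise ConfigurationError(f"unknown initial_field {config.initial_field!r}")


def seed_agents(config: SimulationConfig, grid: StructuredGrid,
                rng: np.random.Generator) -> list:
    """Place the initial population uniformly at random in open CVs,
    rejecting overlaps (and restricting to the bridge for the chamber)."""
    r = config.cells.radius
    lo = grid.origin + r
    hi = grid.upper - r
    if config.placement == "bridge":
        xw = grid.meta["outer_well_length"]
        bl = grid.meta["bridge_length"]
        bw = grid.meta["bridge_width"]
        yc = 0.5 * (grid.origin[1] + grid.upper[1])
        lo = np.maximum(lo, [xw + r, yc - bw / 2 + r, grid.origin[2]])
        hi = np.minimum(hi, [xw + bl - r, yc + bw / 2 - r, grid.upper[2]])
    agents = []
    placed = []
    attempts = 0
    planar = grid.is_planar
    while len(agents) < config.n_cells:
        attempts += 1
        if attempts > 1000 * max(config.n_cells, 1):
            raise ConfigurationError("could not seed agents without overlap")
        p = np.array([
            rng.uniform(lo[a], hi[a]) if grid.axis_active(a)
            else 0.5 * (grid.origin[a] + grid.upper[a])
            for a in range(3)
        ])
        if grid.cv_kind[grid.locate_cv(p)] == CVKind.BLOCKED:
            continue
        if placed and np.min(np.linalg.norm(np.array(placed) - p, axis=1)) < 2 * r:
            continue
        agents.append(Agent(
            id=len(agents),
            position=p,
            direction=random_unit_vector(rng, planar),
            division_class=sample_division_class(config.cells, rng),
            radius=r,
        ))
        placed.append(p)
    return agents


def run_simulation(
    config: SimulationConfig,
    *,
    flow: FlowState | None = None,
    out_dir=None,
    keep_snapshots: bool = False,
) -> SimulationResult:
    """Run a complete coupled scenario.

    ``flow`` may be supplied to reuse a previously solved steady field
    (it only depends on geometry and inlet speed, not on the seed).
    Writes VTK/CSV/JSON outputs to ``out_dir`` when given.
    """
    grid = config.build_grid()
    has_inlet = any(
        p.kind == PatchKind.VELOCITY_INLET and p.inlet_velocity > 0
        for p in grid.patches
    )
    if flow is None:
        if config.solve_flow and has_inlet:
            flow = solve_steady_flow(grid, config.fluid, tolerance=config.flow_tolerance)
        else:
            flow = zero_flow(grid)

    field_state = make_field(grid, config.species, phi=_initial_phi(config, grid))
    rng0 = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                        spawn_key=(0xA11CE,)))
    agents = seed_agents(config, grid, rng0)
    initial_positions = np.array([a.position for a in agents]).reshape(-1, 3)

    params = config.cells
    dt_h = config.cycle_hours
    dt_s = dt_h * HOUR
    records = []
    snapshots = []
    cum_births = cum_deaths = 0
    next_id = len(agents)

    operator = TransportOperator(
        grid, flow, config.species, dt_s,
        substeps=config.transport_substeps, scheme=config.scheme,
    )

    try:
        for cycle in range(1, config.n_cycles + 1):
            # (1) sinks from live agents, (2) implicit transport step
            sinks = assemble_sink_field(
                grid, agents, params.consumption_rate, config.sink_cutoff, field_state
            )
            field_state = operator.step(field_state, sinks)
            if not np.all(np.isfinite(field_state.phi)):
                raise SolverError("non-finite concentration field")

            # (3) sense + agent updates, id order (agents list is id-ordered)
            phi_filled = _fill_blocked(grid, field_state.phi)
            grad_field = _gradient_arrays(grid, phi_filled)
            births = deaths = 0
            for agent in agents:
                if not agent.is_live:
                    continue
                arng = _agent_rng(config.seed, cycle, agent.id)
                localC = _trilinear(grid, phi_filled, agent.position)
                grad = np.array([
                    _trilinear(grid, grad_field[..., d], agent.position)
                    for d in range(3)
                ])
                update_hypoxia(agent, localC, params, dt_h)
                if not agent.is_live:
                    deaths += 1
                    continue
                step_motility(agent, localC, grad, params, dt_h, arng, grid)
            resolve_contacts(agents, params, grid)

            # division (with the pre-division stationary phase)
            new_agents = []
            live = [a for a in agents if a.is_live]
            bond_counts = _bond_counts(live, params)
            for agent, bonds in zip(live, bond_counts):
                if not params.division_enabled:
                    break
                agent.age_since_division += dt_h
                if agent.age_since_division < agent.division_class:
                    continue
                localC = _trilinear(grid, phi_filled, agent.position)
                if (
                    params.division_requires_normoxia
                    and params.chemotaxis_trigger == "below"
                    and _wants_chemotaxis(localC, params)
                ):
                    continue
                if bonds >= params.confluence_bond_count:
                    continue
                if not agent.pending_division:
                    # stop before dividing: one rest period first
                    agent.pending_division = True
                    agent.state = AgentState.ARRESTED
                    agent.rest_clock = max(agent.rest_clock, params.rest_time)
                    continue
                if agent.rest_clock > 1e-12:
                    continue
                arng = _agent_rng(config.seed, cycle, 0x10000000 + agent.id)
                daughter = attempt_division(
                    agent, agents + new_agents, params, arng, grid,
                    localC=localC, next_id=next_id,
                )
                if daughter is not None:
                    new_agents.append(daughter)
                    next_id += 1
                    births += 1
            agents.extend(new_agents)
            if new_agents:
                resolve_contacts(agents, params, grid)

            cum_births += births
            cum_deaths += deaths
            budget = mass_budget(field_state, grid)
            openm = grid.open_mask
            records.append(CycleRecord(
                cycle=cycle,
                time_h=cycle * dt_h,
                n_live=sum(a.is_live for a in agents),
                n_rw=sum(a.state == AgentState.RW for a in agents),
                n_chemo=sum(a.state == AgentState.CHEMO for a in agents),
                n_arrested=sum(a.state == AgentState.ARRESTED for a in agents),
                n_dead=sum(not a.is_live for a in agents),
                n_flagged=sum(a.apoptotic_flag for a in agents),
                births=births,
                deaths=deaths,
                total_mass=field_state.storage(grid),
                min_phi=float(field_state.phi[openm].min()),
                mean_phi=float(field_state.phi[openm].mean()),
                ledger_closure=budget["closure"],
            ))
            if keep_snapshots or (
                config.snapshot_every and cycle % config.snapshot_every == 0
            ):
                snapshots.append((cycle, field_state.phi.copy()))
    except Exception as exc:
        raise type(exc)(
            f"[cycle {len(records) + 1}] {exc}"
        ).with_traceback(exc.__traceback__) from None

    result = SimulationResult(
        config=config, grid=grid, flow=flow, field=field_state, agents=agents,
        records=records, initial_positions=initial_positions, snapshots=snapshots,
    )
    if out_dir is not None:
        from .io_utils import write_outputs

        write_outputs(result, out_dir)
    return result


def run_insall_validation(
    config: SimulationConfig | None = None,
    *,
    seed: int | None = None,
    out_dir=None,
):
    """Run the chamber chemotaxis validation: an attractant run and a
    matched no-attractant control with identical seeds and initial
    positions, 25 simulated hours, followed by a paired two-tailed test
    on the per-cell displacements along the gradient axis (positive
    toward the attractant well).
    """
    from .scenarios import scenario
    from .stats import chemotaxis_report

    if config is None:
        config = scenario("INSALL")
    if config.preset != "INSALL":
        raise ConfigurationError("the validation requires the INSALL preset")
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    control_cfg = dataclasses.replace(
        config,
        name=config.name + "_control",
        species=dataclasses.replace(config.species, initial_concentration=0.0),
    )

    test_run = run_simulation(config, out_dir=None)
    control_run = run_simulation(control_cfg, out_dir=None)

    axis = np.asarray(test_run.grid.meta["attractant_axis"], dtype=float)

    def displacements(run):
        byid = {a.id: a for a in run.agents}
        out = []
        for i, p0 in enumerate(run.initial_positions):
            a = byid[i]
            out.append(float(np.dot(a.position - p0, axis)))
        return np.array(out)

    report = chemotaxis_report(displacements(test_run), displacements(control_run))
    if out_dir is not None:
        from .io_utils import write_outputs, write_insall_report

        write_outputs(test_run, out_dir)
        write_insall_report(report, out_dir)
    return report, test_run, control_run
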