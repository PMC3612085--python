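"""Per-cell behavioral state machine.

Each virtual cell is a non-deformable sphere (radius 10 um) with a small
rule set evaluated once per coupling cycle:

* persistent random walk at 10 um/hr under normoxia, redrawing a uniform
  random direction after every 2 h of motion;
* chemotaxis at 20 um/hr straight up the local concentration gradient
  when the local oxygen drops below 0.0672 mol/m^3 (for attractant-driven
  cells such as MV3 melanoma the trigger is inverted: chemotaxis begins
  once the attractant *exceeds* its critical concentration);
* a hypoxia clock that marks the cell apoptotic after 7 h continuously
  below threshold and kills it after 15 h; full reset on reoxygenation,
  but the apoptotic marker is kept as history;
* division on a stochastic cell-cycle class (18 h: 64 %, 24 h: 32 %,
  32 h: 4 %), blocked at confluence (>= 4 bonded neighbours) or under
  hypoxia, with the daughter placed one diameter away in a random
  direction and a 1 h post-division rest for both;
* hard-sphere contact resolution: overlapping pairs are pushed apart to
  exactly one diameter and newly contacting cells (cell-cell or
  cell-boundary) arrest for 1 h, resuming in a fresh random direction.

Clocks are in hours, positions in metres.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .grid_geometry import CVKind, StructuredGrid

__all__ = [
    "AgentState",
    "Agent",
    "CellRuleParams",
    "sample_division_class",
    "step_motility",
    "update_hypoxia",
    "attempt_division",
    "resolve_contacts",
    "count_bonds",
    "random_unit_vector",
]


class AgentState(IntEnum):
    RW = 0        # normoxic persistent random walk
    CHEMO = 1     # chemotaxing along the gradient
    ARRESTED = 2  # post-collision / peri-division rest
    DEAD = 3


@dataclass
class CellRuleParams:
    """Cell-rule constants; defaults are the oxygen-limited phenotype."""

    rw_speed: float = 10e-6                 # m/hr, persistent random walk
    chemo_speed: float = 20e-6              # m/hr
    persistence_time: float = 2.0           # h of motion between redraws
    rest_time: float = 1.0                  # h, post collision / division
    division_classes: tuple = (18.0, 24.0, 32.0)       # h
    division_probabilities: tuple = (0.64, 0.32, 0.04)
    chemotaxis_threshold: float = 0.0672    # mol/m^3
    chemotaxis_trigger: str = "below"       # "below" (oxygen) | "above" (attractant)
    apoptosis_enabled: bool = True
    apoptotic_trigger_time: float = 7.0     # h of continuous hypoxia -> marker
    apoptotic_death_time: float = 15.0      # h of continuous hypoxia -> death
    death_from_trigger: bool = False        # alternative reading: 15 h after marker
    confluence_bond_count: int = 4
    bond_tolerance: float = 0.05            # fraction of a diameter
    radius: float = 10e-6                   # m
    consumption_rate: float = 12.2          # mol m^-3 hr^-1 per cell
    division_enabled: bool = True
    division_requires_normoxia: bool = True
    arrest_on_contact_in_chemo: bool = True
    placement_retries: int = 24

    def __post_init__(self):
        if abs(sum(self.division_probabilities) - 1.0) > 1e-12:
            raise ConfigurationError("division probabilities must sum to 1")
        if self.rw_speed < 0 or self.chemo_speed < 0:
            raise ConfigurationError("speeds must be >= 0")
        if self.apoptosis_enabled and not (
            self.apoptotic_trigger_time < self.apoptotic_death_time
        ):
            raise ConfigurationError("apoptotic trigger must precede death")
        if self.chemotaxis_trigger not in ("below", "above"):
            raise ConfigurationError("chemotaxis_trigger must be 'below' or 'above'")

    @classmethod
    def mv3(cls, outer_well_concentration: float = 1.0) -> "CellRuleParams":
        """MV3 melanoma phenotype for the chemotaxis-chamber validation:
        chemotaxis at 8 um/hr once the attractant exceeds 10 % of the
        outer-well loading; no oxygen-driven apoptosis; no division."""
        return cls(
            chemo_speed=8e-6,
            chemotaxis_threshold=0.1 * outer_well_concentration,
            chemotaxis_trigger="above",
            apoptosis_enabled=False,
            division_enabled=False,
            consumption_rate=0.0,  # the attractant is not consumed
        )


@dataclass
class Agent:
    """One virtual cell."""

    id: int
    position: np.ndarray
    direction: np.ndarray
    division_class: float
    radius: float = 10e-6
    state: AgentState = AgentState.RW
    apoptotic_flag: bool = False       # hypoxic history marker, persists
    persistence_clock: float = 0.0     # h of motion since last redraw
    rest_clock: float = 0.0            # h of arrest remaining
    hypoxia_clock: float = 0.0         # h continuously below threshold
    age_since_division: float = 0.0    # h
    pending_division: bool = False     # driver bookkeeping (pre-division rest)
    _redraw_on_release: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)

    @property
    def is_live(self) -> bool:
        return self.state != AgentState.DEAD


def random_unit_vector(rng: np.random.Generator, planar: bool = False) -> np.ndarray:
    """Uniform direction on the unit sphere (unit circle when planar)."""
    if planar:
        th = rng.uniform(0.0, 2.0 * np.pi)
        return np.array([np.cos(th), np.sin(th), 0.0])
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def sample_division_class(params: CellRuleParams, rng: np.random.Generator) -> float:
    """Draw a cell-cycle length (h) from the division-probability table."""
    return float(rng.choice(params.division_classes, p=params.division_probabilities))


def _wants_chemotaxis(localC: float, params: CellRuleParams) -> bool:
    if params.chemotaxis_trigger == "below":
        return localC < params.chemotaxis_threshold
    return localC >= params.chemotaxis_threshold


def project_into_domain(grid: StructuredGrid, position, radius: float):
    """Clamp a sphere center to keep it at least one radius inside the box.

    Returns (position, contacted): ``contacted`` is True when clamping was
    needed (boundary contact).  BLOCKED CVs are handled by the caller
    (moves into them are cancelled).
    """
    p = np.asarray(position, dtype=float).copy()
    lo = grid.origin + radius
    hi = grid.upper - radius
    for a in range(3):
        if not grid.axis_active(a):
            # planar mode: keep the agent on the mid-plane
            p[a] = 0.5 * (grid.origin[a] + grid.upper[a])
            continue
        if lo[a] > hi[a]:
            p[a] = 0.5 * (grid.origin[a] + grid.upper[a])
    clamped = np.minimum(np.maximum(p, lo), hi)
    for a in range(3):
        if not grid.axis_active(a):
            clamped[a] = p[a]
    contacted = bool(np.any(np.abs(clamped - p) > 1e-15))
    return clamped, contacted


def _try_move(grid: StructuredGrid, agent: Agent, displacement) -> bool:
    """Apply a displacement; cancel moves ending in a BLOCKED CV and clamp
    at the domain walls.  Returns True if a boundary/wall contact occurred."""
    target = agent.position + displacement
    target, contacted = project_into_domain(grid, target, agent.radius)
    if grid.cv_kind[grid.locate_cv(target)] == CVKind.BLOCKED:
        return True  # stay put: interior wall contact
    agent.position = target
    return contacted


def step_motility(
    agent: Agent,
    localC: float,
    localGrad,
    params: CellRuleParams,
    dt: float,
    rng: np.random.Generator,
    grid: StructuredGrid,
) -> Agent:
    """Advance one agent's motion by one coupling cycle (dt hours).

    Mode selection is purely local: chemotaxis when the trigger condition
    holds (moving up the gradient at ``chemo_speed``), otherwise the
    persistent random walk at ``rw_speed`` with a direction redraw after
    every ``persistence_time`` hours of accumulated motion.  Arrested
    agents sit still, run down their rest clock and resume in a fresh
    random direction.  A move that would exit the domain or enter an
    interior wall arrests the agent for ``rest_time``.
    """
    if agent.state == AgentState.DEAD:
        return agent
    planar = grid.is_planar

    if agent.state == AgentState.ARRESTED:
        agent.rest_clock -= dt
        if agent.rest_clock <= 1e-12:
            agent.rest_clock = 0.0
            agent.state = AgentState.RW
            agent.direction = random_unit_vector(rng, planar)
            agent.persistence_clock = 0.0
        return agent

    contacted = False
    if _wants_chemotaxis(localC, params):
        g = np.asarray(localGrad, dtype=float)
        gnorm = np.linalg.norm(g)
        agent.state = AgentState.CHEMO
        agent.direction = (
            g / gnorm if gnorm > 0 else random_unit_vector(rng, planar)
        )
        contacted = _try_move(grid, agent, agent.direction * params.chemo_speed * dt)
    else:
        if agent.state == AgentState.CHEMO:
            # back to the random walk in a freshly drawn direction
            agent.direction = random_unit_vector(rng, planar)
            agent.persistence_clock = 0.0
        agent.state = AgentState.RW
        contacted = _try_move(grid, agent, agent.direction * params.rw_speed * dt)
        agent.persistence_clock += dt
        if agent.persistence_clock >= params.persistence_time - 1e-12:
            agent.direction = random_unit_vector(rng, planar)
            agent.persistence_clock = 0.0
    if contacted and (params.arrest_on_contact_in_chemo or agent.state == AgentState.RW):
        agent.state = AgentState.ARRESTED
        agent.rest_clock = params.rest_time
    return agent


def update_hypoxia(
    agent: Agent, localC: float, params: CellRuleParams, dt: float
) -> Agent:
    """Advance the hypoxia clock; set the apoptotic marker / kill the cell.

    The clock accumulates continuous time below threshold and fully
    resets on reoxygenation (a rescued cell survives); the apoptotic
    marker, once set, is kept as history.  By default death occurs after
    ``apoptotic_death_time`` hours of continuous hypoxia; the alternative
    reading (death ``apoptotic_death_time`` hours after the marker) is
    available via ``death_from_trigger``.
    """
    if agent.state == AgentState.DEAD or not params.apoptosis_enabled:
        return agent
    if localC < params.chemotaxis_threshold:
        agent.hypoxia_clock += dt
        if agent.hypoxia_clock >= params.apoptotic_trigger_time - 1e-12:
            agent.apoptotic_flag = True
        death_at = params.apoptotic_death_time + (
            params.apoptotic_trigger_time if params.death_from_trigger else 0.0
        )
        if agent.hypoxia_clock >= death_at - 1e-12:
            agent.state = AgentState.DEAD
    else:
        agent.hypoxia_clock = 0.0
    return agent


def count_bonds(agent: Agent, agents, params: CellRuleParams) -> int:
    """Number of live agents bonded to ``agent`` (center distance within
    one diameter plus ``bond_tolerance``)."""
    cutoff = 2.0 * agent.radius * (1.0 + params.bond_tolerance)
    others = [a for a in agents if a.is_live and a.id != agent.id]
    if not others:
        return 0
    pos = np.array([a.position for a in others])
    tree = cKDTree(pos)
    return len(tree.query_ball_point(agent.position, cutoff))


def attempt_division(
    agent: Agent,
    agents,
    params: CellRuleParams,
    rng: np.random.Generator,
    grid: StructuredGrid,
    localC: float | None = None,
    next_id: int | None = None,
) -> Agent | None:
    """Divide an agent whose cell cycle has elapsed.

    Returns the daughter, or None when division is not possible this
    cycle (confluence, hypoxia, or no admissible placement — the latter
    simply defers to the next cycle).  The daughter is placed one
    diameter from the parent in a uniformly random direction that lands
    inside the domain without overlapping a live neighbour; both cells
    arrest for ``rest_time`` and restart fresh cycles.
    """
    if not agent.is_live or not params.division_enabled:
        return None
    if agent.age_since_division < agent.division_class - 1e-12:
        return None
    if count_bonds(agent, agents, params) >= params.confluence_bond_count:
        return None
    if (
        params.division_requires_normoxia
        and localC is not None
        and _wants_chemotaxis(localC, params)
        and params.chemotaxis_trigger == "below"
    ):
        return None
    planar = grid.is_planar
    r = agent.radius
    live_pos = np.array(
        [a.position for a in agents if a.is_live and a.id != agent.id]
    )
    tree = cKDTree(live_pos) if len(live_pos) else None
    for _ in range(params.placement_retries):
        d = random_unit_vector(rng, planar)
        cand = agent.position + d * 2.0 * r
        cand, contacted = project_into_domain(grid, cand, r)
        if contacted:
            continue
        if grid.cv_kind[grid.locate_cv(cand)] == CVKind.BLOCKED:
            continue
        if tree is not None and tree.query_ball_point(cand, 2.0 * r * (1 - 1e-9)):
            continue
        if np.linalg.norm(cand - agent.position) < 2.0 * r * (1 - 1e-9):
            continue
        daughter = Agent(
            id=next_id if next_id is not None else -1,
            position=cand,
            direction=random_unit_vector(rng, planar),
            division_class=sample_division_class(params, rng),
            radius=r,
            state=AgentState.ARRESTED,
            rest_clock=params.rest_time,
        )
        agent.state = AgentState.ARRESTED
        agent.rest_clock = params.rest_time
        agent.age_since_division = 0.0
        agent.division_class = sample_division_class(params, rng)
        agent.pending_division = False
        return daughter
    return None  # caged: defer to the next cycle


def resolve_contacts(agents, params: CellRuleParams, grid: StructuredGrid,
                     max_passes: int = 25):
    """Hard-sphere overlap resolution plus contact arrest.

    Overlapping live pairs are pushed apart symmetrically along their
    center line to exactly one diameter; agents pushed out of the box are
    clamped back.  Every live agent involved in a new cell or boundary
    contact this cycle is arrested for ``rest_time`` and will resume in a
    fresh random direction.  Returns the (mutated) agent list.
    """
    live = [a for a in agents if a.is_live]
    if not live:
        return agents
    r = params.radius
    target = 2.0 * r
    contacted: set[int] = set()
    for _ in range(max_passes):
        pos = np.array([a.position for a in live])
        pairs = cKDTree(pos).query_pairs(target * (1.0 - 1e-12), output_type="ndarray")
        if len(pairs) == 0:
            break
        for i, j in pairs:
            a, b = live[int(i)], live[int(j)]
            dvec = b.position - a.position
            dist = np.linalg.norm(dvec)
            if dist < 1e-15:
                dvec = random_unit_vector(
                    np.random.default_rng(a.id * 65537 + b.id), grid.is_planar
                )
                dist = 1e-15
            push = 0.5 * (target - dist) * dvec / dist
            a.position = a.position - push
            b.position = b.position + push
            contacted.add(a.id)
            contacted.add(b.id)
        for a in live:
            p, hit = project_into_domain(grid, a.position, a.radius)
            a.position = p
            if hit:
                contacted.add(a.id)
    for a in live:
        p, hit = project_into_domain(grid, a.position, a.radius)
        a.position = p
        if hit:
            contacted.add(a.id)
    for a in live:
        if a.id in contacted and a.state != AgentState.ARRESTED:
            if a.state == AgentState.CHEMO and not params.arrest_on_contact_in_chemo:
                continue
            a.state = AgentState.ARRESTED
            a.rest_clock = params.rest_time
    return agents
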