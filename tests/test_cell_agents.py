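"""Cell rule set: division statistics, motility, hypoxia clocks, contacts."""

import collections
import copy

import numpy as np
import pytest

from perfusim import (
    Agent,
    AgentState,
    CellRuleParams,
    StructuredGrid,
    attempt_division,
    count_bonds,
    resolve_contacts,
    sample_division_class,
    step_motility,
    update_hypoxia,
)
from perfusim.cell_agents import random_unit_vector

UM = 1e-6
DT = 0.25  # coupling cycle, hours


@pytest.fixture()
def box():
    g = StructuredGrid(40, 40, 8, 2.5e-5, 2.5e-5, 2.5e-5, origin=np.zeros(3))
    g.attach_patches([])
    return g


def _agent(pos=(5e-4, 5e-4, 1e-4), direction=(1.0, 0.0, 0.0), **kw):
    return Agent(id=kw.pop("id", 0), position=np.array(pos, dtype=float),
                 direction=np.array(direction, dtype=float),
                 division_class=kw.pop("division_class", 18.0), **kw)


class TestDivisionSampling:
    def test_distribution_matches_table(self, params):
        """10,000 draws recover 64/32/4% within 3-sigma binomial bands."""
        rng = np.random.default_rng(42)
        draws = collections.Counter(
            sample_division_class(params, rng) for _ in range(10_000)
        )
        assert draws[18.0] / 10_000 == pytest.approx(0.64, abs=0.015)
        assert draws[24.0] / 10_000 == pytest.approx(0.32, abs=0.014)
        assert draws[32.0] / 10_000 == pytest.approx(0.04, abs=0.006)

    def test_reproducible_under_fixed_seed(self, params):
        a = [sample_division_class(params, np.random.default_rng(7)) for _ in range(50)]
        b = [sample_division_class(params, np.random.default_rng(7)) for _ in range(50)]
        assert a == b


class TestMotility:
    def test_dead_agent_never_moves(self, box, params, rng):
        a = _agent(state=AgentState.DEAD)
        p0 = a.position.copy()
        for localC in (0.0, 0.21):
            step_motility(a, localC, np.array([1.0, 0, 0]), params, DT, rng, box)
        assert np.array_equal(a.position, p0)

    def test_chemotaxis_speed_and_direction(self, box, params, rng):
        """Below threshold: straight up the gradient at 20 um/hr."""
        a = _agent()
        p0 = a.position.copy()
        for _ in range(4):  # 1 h
            step_motility(a, 0.05, np.array([3.0, 0, 0]), params, DT, rng, box)
        disp = a.position - p0
        assert disp[0] == pytest.approx(20 * UM, rel=1e-12)
        assert abs(disp[1]) < 1e-18 and abs(disp[2]) < 1e-18
        assert a.state == AgentState.CHEMO

    def test_random_walk_speed_and_persistence(self, box, params):
        """10 h of normoxic motion: path 100 um, direction changes every 2 h."""
        rng = np.random.default_rng(3)
        a = _agent()
        dirs, path, prev = [], 0.0, a.position.copy()
        for _ in range(40):  # 10 h
            dirs.append(a.direction.copy())
            step_motility(a, 0.21, np.zeros(3), params, DT, rng, box)
            path += np.linalg.norm(a.position - prev)
            prev = a.position.copy()
        assert path == pytest.approx(100 * UM, rel=1e-9)
        changes = [
            i for i in range(1, 40)
            if not np.allclose(dirs[i], dirs[i - 1])
        ]
        assert changes == [8, 16, 24, 32]  # every 2 h of motion

    def test_chemo_reverts_to_random_walk_when_rescued(self, box, params, rng):
        a = _agent()
        step_motility(a, 0.05, np.array([1.0, 0, 0]), params, DT, rng, box)
        assert a.state == AgentState.CHEMO
        step_motility(a, 0.21, np.zeros(3), params, DT, rng, box)
        assert a.state == AgentState.RW

    def test_attractant_mode_triggers_above_threshold(self, box, rng):
        mv3 = CellRuleParams.mv3(outer_well_concentration=1.0)
        a = _agent()
        p0 = a.position.copy()
        for _ in range(4):
            step_motility(a, 0.5, np.array([1.0, 0, 0]), mv3, DT, rng, box)
        assert a.state == AgentState.CHEMO
        assert (a.position - p0)[0] == pytest.approx(8 * UM, rel=1e-12)
        # below 10% of the loading: persistent random walk
        b = _agent(id=1)
        step_motility(b, 0.05, np.array([1.0, 0, 0]), mv3, DT, rng, box)
        assert b.state == AgentState.RW

    def test_arrested_agent_rests_then_resumes(self, box, params):
        rng = np.random.default_rng(11)
        a = _agent(state=AgentState.ARRESTED)
        a.rest_clock = 1.0
        p0 = a.position.copy()
        for _ in range(4):
            step_motility(a, 0.21, np.zeros(3), params, DT, rng, box)
        assert np.array_equal(a.position, p0)   # never moved while resting
        assert a.state == AgentState.RW          # released with a fresh direction
        step_motility(a, 0.21, np.zeros(3), params, DT, rng, box)
        assert not np.array_equal(a.position, p0)

    def test_boundary_contact_arrests(self, box, params, rng):
        a = _agent(pos=(1.2e-5, 5e-4, 1e-4), direction=(-1.0, 0.0, 0.0))
        step_motility(a, 0.21, np.zeros(3), params, DT, rng, box)
        assert a.state == AgentState.ARRESTED
        assert a.position[0] == pytest.approx(a.radius)


class TestHypoxia:
    def test_normoxic_agent_keeps_zero_clock(self, params):
        a = _agent()
        for _ in range(100):
            update_hypoxia(a, 0.21, params, DT)
        assert a.hypoxia_clock == 0.0 and not a.apoptotic_flag and a.is_live

    def test_marker_at_7h_death_at_15h(self, params):
        a = _agent()
        flagged = died = None
        for k in range(1, 81):
            update_hypoxia(a, 0.0, params, DT)
            t = k * DT
            if a.apoptotic_flag and flagged is None:
                flagged = t
            if not a.is_live and died is None:
                died = t
        assert flagged == pytest.approx(7.0, abs=DT)
        assert died == pytest.approx(15.0, abs=DT)

    def test_rescue_resets_clock_but_marker_persists(self, params):
        """6 h hypoxia, rescue, then 14 h hypoxia: alive throughout; the
        marker appears 7 h after the second onset."""
        a = _agent()
        for _ in range(24):  # 6 h hypoxic
            update_hypoxia(a, 0.0, params, DT)
        assert not a.apoptotic_flag
        update_hypoxia(a, 0.21, params, DT)  # rescued
        assert a.hypoxia_clock == 0.0
        flag_time = None
        for k in range(1, 57):  # 14 h hypoxic again
            update_hypoxia(a, 0.0, params, DT)
            if a.apoptotic_flag and flag_time is None:
                flag_time = k * DT
        assert a.is_live
        assert flag_time == pytest.approx(7.0, abs=DT)
        # the marker is history: it survives a second rescue
        update_hypoxia(a, 0.21, params, DT)
        assert a.apoptotic_flag

    def test_alternative_death_reading_is_additive(self):
        params = CellRuleParams(death_from_trigger=True)
        a = _agent()
        died = None
        for k in range(1, 120):
            update_hypoxia(a, 0.0, params, DT)
            if not a.is_live:
                died = k * DT
                break
        assert died == pytest.approx(22.0, abs=DT)


class TestDivision:
    def test_confluent_agent_does_not_divide(self, box, params, rng):
        center = _agent(age_since_division=20.0)
        neighbors = [
            _agent(id=i + 1, pos=center.position + 2 * center.radius * v)
            for i, v in enumerate([
                np.array([1.0, 0, 0]), np.array([-1.0, 0, 0]),
                np.array([0, 1.0, 0]), np.array([0, -1.0, 0]),
            ])
        ]
        assert count_bonds(center, [center] + neighbors, params) == 4
        assert attempt_division(center, [center] + neighbors, params, rng, box,
                                localC=0.21) is None

    def test_isolated_agent_divides_at_one_diameter(self, box, params, rng):
        a = _agent(age_since_division=18.0)
        d = attempt_division(a, [a], params, rng, box, localC=0.21, next_id=1)
        assert d is not None
        assert np.linalg.norm(d.position - a.position) == pytest.approx(
            2 * a.radius, rel=1e-9
        )
        assert a.state == AgentState.ARRESTED and d.state == AgentState.ARRESTED
        assert a.rest_clock == params.rest_time == d.rest_clock
        assert a.age_since_division == 0.0

    def test_hypoxic_agent_defers_division(self, box, params, rng):
        a = _agent(age_since_division=18.0)
        assert attempt_division(a, [a], params, rng, box, localC=0.01) is None

    def test_fully_caged_agent_defers(self, box, params, rng):
        """12 contacting neighbours leave no admissible daughter position."""
        center = _agent(age_since_division=18.0)
        # fcc-like shell of 12 at exactly one diameter
        shell = []
        k = 0
        for v in [
            (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0),
            (1, 0, 1), (1, 0, -1), (-1, 0, 1), (-1, 0, -1),
            (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
        ]:
            u = np.array(v, dtype=float) / np.sqrt(2)
            k += 1
            shell.append(_agent(id=k, pos=center.position + 2 * center.radius * u))
        loose = CellRuleParams(confluence_bond_count=20)  # isolate the caging effect
        assert attempt_division(center, [center] + shell, loose, rng, box,
                                localC=0.21) is None


class TestContacts:
    def test_separated_pair_untouched(self, box, params):
        a = _agent(); b = _agent(id=1, pos=a.position + np.array([3e-5, 0, 0]))
        pa, pb = a.position.copy(), b.position.copy()
        resolve_contacts([a, b], params, box)
        assert np.array_equal(a.position, pa) and np.array_equal(b.position, pb)
        assert a.state == AgentState.RW

    def test_overlapping_pair_pushed_to_contact_and_arrested(self, box, params):
        a = _agent()
        b = _agent(id=1, pos=a.position + np.array([1.5e-5, 0, 0]))  # 1.5 r apart
        resolve_contacts([a, b], params, box)
        assert np.linalg.norm(a.position - b.position) == pytest.approx(
            2 * a.radius, rel=1e-9
        )
        assert a.state == b.state == AgentState.ARRESTED
        assert a.rest_clock == 1.0

    def test_wall_penetration_projected_and_arrested(self, box, params):
        a = _agent(pos=(2e-6, 5e-4, 1e-4))  # center closer than r to the wall
        resolve_contacts([a], params, box)
        assert a.position[0] == pytest.approx(a.radius)
        assert a.state == AgentState.ARRESTED

    def test_dead_agents_are_inert(self, box, params):
        a = _agent(state=AgentState.DEAD)
        b = _agent(id=1, pos=a.position + np.array([5e-6, 0, 0]))
        resolve_contacts([a, b], params, box)
        assert np.linalg.norm(a.position - b.position) == pytest.approx(5e-6)

    def test_no_live_overlaps_after_resolution(self, box, params, rng):
        from perfusim import make_fixture

        agents = make_fixture("agent_cloud", {"n": 50}, rng=5)["agents"]
        # shove them together to create overlaps
        for a in agents:
            a.position = a.position * 0.5 + np.array([2.5e-4, 2.5e-4, 5e-5])
        resolve_contacts(agents, params, box)
        pos = np.array([a.position for a in agents])
        from scipy.spatial.distance import pdist

        assert pdist(pos).min() >= 2 * params.radius * (1 - 1e-9)


class TestBonds:
    def test_isolated_agent_has_no_bonds(self, params):
        a = _agent()
        assert count_bonds(a, [a], params) == 0

    def test_matches_brute_force_on_random_cloud(self, params):
        from perfusim import make_fixture

        agents = make_fixture("agent_cloud", {"n": 50, "box": (2e-4, 2e-4, 1e-4)},
                              rng=9)["agents"]
        cutoff = 2 * params.radius * (1 + params.bond_tolerance)
        pos = np.array([a.position for a in agents])
        for a in agents[:10]:
            brute = sum(
                1 for b in agents
                if b.id != a.id and np.linalg.norm(b.position - a.position) <= cutoff
            )
            assert count_bonds(a, agents, params) == brute


class TestWalkStatistics:
    def test_msd_matches_run_and_tumble_monte_carlo(self, box, params):
        """Long-time effective diffusivity of the implemented walk matches a
        brute-force ideal run-and-tumble at the same speed/persistence
        within 10%."""
        n, hours = 400, 60
        steps = int(hours / DT)
        # implemented walk, free space (no collisions: agents stepped alone)
        disp2 = []
        for i in range(n):
            rng = np.random.default_rng(1000 + i)
            a = _agent(id=i)
            a.direction = random_unit_vector(rng)
            p0 = a.position.copy()
            for _ in range(steps):
                step_motility(a, 0.21, np.zeros(3), params, DT, rng, box)
            disp2.append(np.sum((a.position - p0) ** 2))
        msd_impl = np.mean(disp2)

        # independent Monte-Carlo of ideal run-and-tumble: straight segments
        # of length speed*persistence in fresh uniform directions
        rng = np.random.default_rng(77)
        seg = params.rw_speed * params.persistence_time
        nseg = int(hours / params.persistence_time)
        vecs = rng.normal(size=(n, nseg, 3))
        vecs /= np.linalg.norm(vecs, axis=2, keepdims=True)
        ends = seg * vecs.sum(axis=1)
        msd_mc = float(np.mean(np.sum(ends**2, axis=1)))
        assert msd_impl == pytest.approx(msd_mc, rel=0.10)

    def test_chemotactic_displacement_increases_linearly(self, box, params, rng):
        """In a static sub-threshold linear field the gradient-axis
        displacement grows strictly at 20 um/hr."""
        a = _agent()
        xs = [a.position[0]]
        for _ in range(20):
            step_motility(a, 0.01, np.array([5.0, 0, 0]), params, DT, rng, box)
            xs.append(a.position[0])
        diffs = np.diff(xs)
        assert np.all(diffs > 0)
        assert np.allclose(diffs, params.chemo_speed * DT, rtol=1e-9)
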