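"""Scenario presets, fixtures, the paired test, and readers/writers."""

import dataclasses

import numpy as np
import pytest
from scipy import special
from scipy import stats as sps

from perfusim import (
    ConfigurationError,
    make_fixture,
    one_sample_two_tailed_test,
    paired_two_tailed_test,
    scenario,
)
from perfusim.io_utils import (
    load_config,
    read_agents_csv,
    save_config,
    write_agents_csv,
    write_vtk_structured_points,
)

# device constants as published (Tables of bioreactor and cell variables)
PUBLISHED = {
    "oxygen_diffusivity_m2_per_hr": 1e-5,
    "inlet_concentration": 0.21,
    "porosity": 0.75,
    "permeability_m2": 1e-10,
    "density": 1000.0,
    "viscosity": 1e-3,
    "device_speeds_per_hr": {"CASE1": 0.001, "CASE2": 0.01,
                             "CASE3": 0.001, "CASE4": 0.01},
    "cells": {"CASE1": 100, "CASE2": 100, "CASE3": 5, "CASE4": 5},
    "geometry": {"CASE1": "GEOMETRY_A", "CASE2": "GEOMETRY_A",
                 "CASE3": "GEOMETRY_B", "CASE4": "GEOMETRY_B"},
    "durations_h": {"CASE1": 96.0, "CASE2": 96.0, "CASE3": 144.0, "CASE4": 144.0},
    "division_classes": (18.0, 24.0, 32.0),
    "division_probabilities": (0.64, 0.32, 0.04),
    "rw_speed_um_hr": 10.0,
    "chemo_speed_um_hr": 20.0,
    "mv3_chemo_speed_um_hr": 8.0,
    "hypoxia_threshold": 0.0672,
    "persistence_h": 2.0,
    "rest_h": 1.0,
    "apoptotic_trigger_h": 7.0,
    "apoptotic_death_h": 15.0,
    "confluence_bonds": 4,
    "consumption_rate_per_hr": 12.2,
    "cell_radius_um": 10.0,
    "cycle_h": 0.25,
    "fbs_diffusivity_m2_s": 8.705e-11,
    "insall_duration_h": 25.0,
    "bridge_length_m": 5e-4,
}


class TestPresets:
    @pytest.mark.parametrize("name", ["CASE1", "CASE2", "CASE3", "CASE4"])
    def test_bioreactor_cases_match_published_tables(self, name):
        cfg = scenario(name)
        assert cfg.preset == PUBLISHED["geometry"][name]
        assert cfg.n_cells == PUBLISHED["cells"][name]
        assert cfg.duration_hours == PUBLISHED["durations_h"][name]
        assert cfg.cycle_hours == PUBLISHED["cycle_h"]
        # inlet speed: device per-hour figure, stored in SI
        assert cfg.inlet_velocity * 3600.0 == pytest.approx(
            PUBLISHED["device_speeds_per_hr"][name]
        )
        assert cfg.species.diffusivity * 3600.0 == pytest.approx(
            PUBLISHED["oxygen_diffusivity_m2_per_hr"]
        )
        assert cfg.species.inlet_concentration == PUBLISHED["inlet_concentration"]
        cells = cfg.cells
        assert cells.division_classes == PUBLISHED["division_classes"]
        assert cells.division_probabilities == PUBLISHED["division_probabilities"]
        assert cells.rw_speed * 1e6 == PUBLISHED["rw_speed_um_hr"]
        assert cells.chemo_speed * 1e6 == PUBLISHED["chemo_speed_um_hr"]
        assert cells.chemotaxis_threshold == PUBLISHED["hypoxia_threshold"]
        assert cells.persistence_time == PUBLISHED["persistence_h"]
        assert cells.rest_time == PUBLISHED["rest_h"]
        assert cells.apoptotic_trigger_time == PUBLISHED["apoptotic_trigger_h"]
        assert cells.apoptotic_death_time == PUBLISHED["apoptotic_death_h"]
        assert cells.confluence_bond_count == PUBLISHED["confluence_bonds"]
        assert cells.consumption_rate == PUBLISHED["consumption_rate_per_hr"]
        assert cells.radius * 1e6 == PUBLISHED["cell_radius_um"]
        grid = cfg.build_grid()
        assert np.all(grid.porosity == PUBLISHED["porosity"])
        assert np.all(grid.permeability == PUBLISHED["permeability_m2"])
        assert cfg.fluid.density == PUBLISHED["density"]
        assert cfg.fluid.viscosity == PUBLISHED["viscosity"]

    def test_insall_preset_mv3_rules(self):
        cfg = scenario("INSALL")
        assert cfg.duration_hours == PUBLISHED["insall_duration_h"]
        assert cfg.species.diffusivity == PUBLISHED["fbs_diffusivity_m2_s"]
        assert cfg.cells.chemo_speed * 1e6 == PUBLISHED["mv3_chemo_speed_um_hr"]
        assert cfg.cells.chemotaxis_trigger == "above"
        assert cfg.cells.chemotaxis_threshold == pytest.approx(
            0.1 * cfg.species.initial_concentration
        )
        assert not cfg.cells.apoptosis_enabled and not cfg.cells.division_enabled
        grid = cfg.build_grid()
        assert grid.meta["bridge_length"] == PUBLISHED["bridge_length_m"]

    def test_unknown_scenario_raises(self):
        with pytest.raises(ConfigurationError):
            scenario("CASE9")


class TestFixtures:
    def test_linear_field_gradient_by_construction(self):
        from perfusim import sample_gradient

        fx = make_fixture("linear_field", {"slope": 42.0})
        g = fx["grid"]
        p = g.cell_center((g.nx // 2, g.ny // 2, g.nz // 2))
        grad = sample_gradient(fx["field"], g, p)
        assert grad[0] == pytest.approx(42.0, rel=1e-9)
        assert abs(grad[1]) < 1e-9 and abs(grad[2]) < 1e-9

    def test_agent_cloud_is_reproducible_and_non_overlapping(self):
        a = make_fixture("agent_cloud", {"n": 30}, rng=4)["agents"]
        b = make_fixture("agent_cloud", {"n": 30}, rng=4)["agents"]
        assert all(np.array_equal(x.position, y.position) for x, y in zip(a, b))
        pos = np.array([x.position for x in a])
        from scipy.spatial.distance import pdist

        assert pdist(pos).min() >= 2 * a[0].radius

    def test_unknown_fixture_raises(self):
        with pytest.raises(ConfigurationError):
            make_fixture("mystery")


class TestPairedTest:
    def test_identical_pairs_are_not_significant(self):
        x = np.arange(1.0, 9.0)
        res = paired_two_tailed_test(x, x)
        assert res.p_value == 1.0 and not res.significant

    def test_hand_computed_example(self):
        """differences (1..5): t = 3/(1.5811/sqrt 5) ~ 4.243, p ~ 0.0132."""
        y = np.zeros(5)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = paired_two_tailed_test(x, y)
        assert res.statistic == pytest.approx(4.2426, abs=2e-4)
        assert res.p_value == pytest.approx(0.0132, abs=2e-4)
        assert res.significant

    def test_strongly_directed_sample_is_significant(self, rng):
        x = rng.uniform(5.0, 15.0, 20)
        res = paired_two_tailed_test(x, np.zeros(20))
        assert res.significant and res.p_value < 0.05

    def test_matches_brute_force_t_cdf(self, rng):
        """p-value agrees with the incomplete-beta form of the t CDF and
        with the library implementation to 1e-9."""
        for n in (5, 12, 40):
            x = rng.normal(0.3, 1.0, n)
            y = rng.normal(0.0, 1.0, n)
            res = paired_two_tailed_test(x, y)
            d = x - y
            t = res.statistic
            df = n - 1
            p_beta = special.betainc(df / 2, 0.5, df / (df + t * t))
            assert res.p_value == pytest.approx(p_beta, abs=1e-9)
            ref = sps.ttest_rel(x, y)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-9)

    def test_zero_variance_conventions(self):
        x = np.full(5, 2.0)
        res = paired_two_tailed_test(x, np.zeros(5))
        assert res.p_value == 0.0 and np.isinf(res.statistic)
        res2 = paired_two_tailed_test(x, x)
        assert res2.p_value == 1.0

    def test_wilcoxon_alternative(self, rng):
        x = rng.uniform(5.0, 15.0, 20)
        res = paired_two_tailed_test(x, np.zeros(20), method="wilcoxon")
        assert res.significant

    def test_input_validation(self):
        with pytest.raises(ConfigurationError):
            paired_two_tailed_test([1.0, 2.0], [1.0])
        with pytest.raises(ConfigurationError):
            paired_two_tailed_test([1.0, 2.0], [1.0, np.nan])

    def test_one_sample_unbiased_control(self, rng):
        x = rng.normal(0.0, 1.0, 25)
        res = one_sample_two_tailed_test(x)
        ref = sps.ttest_1samp(x, 0.0)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)


class TestIO:
    def test_vtk_file_structure(self, tmp_path, open_box_grid):
        g = open_box_grid
        data = {"oxygen": np.random.default_rng(0).uniform(0, 1, g.shape)}
        path = write_vtk_structured_points(tmp_path / "f.vtk", g, data)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("# vtk DataFile")
        assert "DATASET STRUCTURED_POINTS" in lines
        assert f"DIMENSIONS {g.nx + 1} {g.ny + 1} {g.nz + 1}" in lines
        assert f"CELL_DATA {g.n_cells}" in lines
        i = lines.index("LOOKUP_TABLE default")
        values = np.array([float(v) for v in lines[i + 1: i + 1 + g.n_cells]])
        # x-fastest ordering round-trips the array
        assert np.allclose(values.reshape(g.shape[::-1]).transpose(2, 1, 0),
                           data["oxygen"])

    def test_agents_csv_round_trip(self, tmp_path):
        agents = make_fixture("agent_cloud", {"n": 12}, rng=2)["agents"]
        path = write_agents_csv(tmp_path / "agents.csv", agents, cycle=3, time_h=0.75)
        df = read_agents_csv(path)
        assert len(df) == 12
        assert np.allclose(df["x_m"], [a.position[0] for a in agents])
        assert (df["state"] == "RW").all()
        assert (df["cycle"] == 3).all()

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = scenario("CASE3", seed=17)
        path = save_config(cfg, tmp_path / "cfg.yaml")
        loaded = load_config(path)
        assert loaded == cfg

    def test_bad_config_raises(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("preset: GEOMETRY_A\nnonsense_key: 1\n")
        with pytest.raises(ConfigurationError):
            load_config(p)
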