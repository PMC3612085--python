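"""Readers and writers: legacy-ASCII VTK, CSV tables, JSON summaries, YAML configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cell_agents import AgentState, CellRuleParams
from .errors import ConfigurationError
from .flow_solver import FluidProperties
from .grid_geometry import StructuredGrid
from .species_transport import SpeciesProperties

__all__ = [
    "write_vtk_structured_points",
    "write_agents_csv",
    "read_agents_csv",
    "write_outputs",
    "write_insall_report",
    "save_config",
    "load_config",
]

AGENT_COLUMNS = [
    "cycle", "time_h", "id", "x_m", "y_m", "z_m", "state",
    "apoptotic_flag", "hypoxia_clock_h", "division_class_h",
]


def write_vtk_structured_points(path, grid: StructuredGrid, cell_data: dict) -> Path:
    """Write CV-centered fields as a legacy-ASCII VTK structured-points file.

    Scalars are written as CELL_DATA on an (nx+1, ny+1, nz+1) point
    lattice; arrays with a trailing dimension of 3 are written as VECTORS.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = grid.shape
    lines = [
        "# vtk DataFile Version 3.0",
        "perfusim field snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"ORIGIN {grid.origin[0]:.9e} {grid.origin[1]:.9e} {grid.origin[2]:.9e}",
        f"SPACING {grid.dx:.9e} {grid.dy:.9e} {grid.dz:.9e}",
        f"CELL_DATA {grid.n_cells}",
    ]
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        if arr.ndim == 4 and arr.shape[-1] == 3:
            lines.append(f"VECTORS {name} double")
            # VTK cell ordering is x-fastest
            flat = arr.transpose(2, 1, 0, 3).reshape(-1, 3)
            lines += [f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}" for v in flat]
        else:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            flat = arr.transpose(2, 1, 0).reshape(-1)
            lines += [f"{v:.9e}" for v in flat]
    path.write_text("\n".join(lines) + "\n")
    return path


def agents_frame(agents, cycle: int = 0, time_h: float = 0.0) -> pd.DataFrame:
    rows = [
        {
            "cycle": cycle,
            "time_h": time_h,
            "id": a.id,
            "x_m": a.position[0],
            "y_m": a.position[1],
            "z_m": a.position[2],
            "state": AgentState(a.state).name,
            "apoptotic_flag": bool(a.apoptotic_flag),
            "hypoxia_clock_h": a.hypoxia_clock,
            "division_class_h": a.division_class,
        }
        for a in agents
    ]
    return pd.DataFrame(rows, columns=AGENT_COLUMNS)


def write_agents_csv(path, agents, cycle: int = 0, time_h: float = 0.0) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    agents_frame(agents, cycle, time_h).to_csv(path, index=False)
    return path


def read_agents_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_outputs(result, out_dir) -> dict:
    """Write a run's products: VTK snapshots, agents CSV, cycle records CSV
    and a JSON summary with the config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    files["final_field"] = str(write_vtk_structured_points(
        out / "field_final.vtk", result.grid,
        {
            result.config.species.name: result.field.phi,
            "pressure": result.flow.pressure,
            "velocity": result.flow.velocity,
            "speed": np.linalg.norm(result.flow.velocity, axis=-1),
            "cv_kind": result.grid.cv_kind.astype(float),
            "porosity": result.grid.porosity,
        },
    ))
    for cycle, phi in result.snapshots:
        write_vtk_structured_points(
            out / f"field_{cycle:05d}.vtk", result.grid,
            {result.config.species.name: phi},
        )
    t_h = result.records[-1].time_h if result.records else 0.0
    cyc = result.records[-1].cycle if result.records else 0
    files["agents"] = str(write_agents_csv(out / "agents_final.csv",
                                           result.agents, cyc, t_h))
    rec = result.records_frame
    rec.to_csv(out / "cycle_records.csv", index=False)
    files["records"] = str(out / "cycle_records.csv")
    from .species_transport import mass_budget

    summary = {
        "config": config_to_dict(result.config),
        "seed": result.config.seed,
        "cycles_run": len(result.records),
        "final_live": int(sum(a.is_live for a in result.agents)),
        "final_dead": int(sum(not a.is_live for a in result.agents)),
        "mass_budget": mass_budget(result.field, result.grid),
        "continuity_residual": result.flow.continuity_residual,
        "units": {"length": "m", "time": "s (fields) / h (records)",
                  "concentration": "mol/m^3"},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    files["summary"] = str(out / "summary.json")
    return files


def write_insall_report(report, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "method": report.method,
        "statistic": report.statistic,
        "p_value": report.p_value,
        "significant": report.significant,
        "mean_difference_m": report.mean_difference,
        "test_displacements_m": list(map(float, report.test_displacements)),
        "control_displacements_m": list(map(float, report.control_displacements)),
        **report.extra,
    }
    path = out / "chemotaxis_report.json"
    path.write_text(json.dumps(payload, indent=2, default=float))
    return path


# ---------------------------------------------------------------------------
# config (de)serialization
# ---------------------------------------------------------------------------

def config_to_dict(config) -> dict:
    d = dataclasses.asdict(config)
    for key in ("fluid", "species", "cells"):
        d[key] = dataclasses.asdict(getattr(config, key))
    d["resolution"] = list(config.resolution)
    d["cells"]["division_classes"] = list(config.cells.division_classes)
    d["cells"]["division_probabilities"] = list(config.cells.division_probabilities)
    return d


def save_config(config, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
    return path


def load_config(path):
    from .coupling_driver import SimulationConfig

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} is not a mapping")
    kwargs = dict(raw)
    if "fluid" in kwargs:
        kwargs["fluid"] = FluidProperties(**kwargs["fluid"])
    if "species" in kwargs:
        kwargs["species"] = SpeciesProperties(**kwargs["species"])
    if "cells" in kwargs:
        cells = dict(kwargs["cells"])
        for key in ("division_classes", "division_probabilities"):
            if key in cells:
                cells[key] = tuple(cells[key])
        kwargs["cells"] = CellRuleParams(**cells)
    if "resolution" in kwargs:
        kwargs["resolution"] = tuple(kwargs["resolution"])
    try:
        return SimulationConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"bad config file {path}: {exc}") from None
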