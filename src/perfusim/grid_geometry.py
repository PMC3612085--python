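"""Structured Cartesian control-volume grids and geometry presets.

The simulator works on axis-aligned boxes divided into ``nx * ny * nz``
control volumes (CVs).  Each CV is tagged FLUID (free medium), POROUS
(scaffold, with a porosity and a permeability entering the momentum
equation in a Darcian sense) or BLOCKED (solid wall interior to the
bounding box, used by the chemotaxis-chamber preset).  Boundary faces of
the box are grouped into named patches (velocity inlet, pressure outlet,
wall); any boundary face not covered by an explicit patch is a wall.

Conventions
-----------
* SI units (metres) everywhere; agent positions are continuous.
* 0-based CV indices; CV ``(i, j, k)`` owns the half-open box
  ``[origin + i*d, origin + (i+1)*d)`` per axis, so every interior point
  maps to exactly one CV.  Points exactly on the upper domain boundary
  are assigned to the last CV.
* An axis with a single CV is treated as invariant (symmetric): ``nz=1``
  gives a planar (2D) domain, ``ny=nz=1`` a 1D column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable

import numpy as np

from .errors import ConfigurationError, OutOfDomainError

__all__ = [
    "CVKind",
    "PatchKind",
    "BoundaryPatch",
    "StructuredGrid",
    "GeometryPreset",
    "build_grid",
    "locate_cv",
    "PRESETS",
]


class CVKind(IntEnum):
    FLUID = 0
    POROUS = 1
    BLOCKED = 2


class PatchKind(IntEnum):
    WALL = 0
    VELOCITY_INLET = 1
    PRESSURE_OUTLET = 2


#: face name -> (axis, side) with side 0 = low boundary, 1 = high boundary
FACES = {
    "-x": (0, 0),
    "+x": (0, 1),
    "-y": (1, 0),
    "+y": (1, 1),
    "-z": (2, 0),
    "+z": (2, 1),
}


def face_tangent_axes(face: str) -> tuple[int, int]:
    """The two in-face axes, in ascending axis order."""
    axis, _ = FACES[face]
    return tuple(a for a in (0, 1, 2) if a != axis)  # type: ignore[return-value]


@dataclass
class BoundaryPatch:
    """A rectangular group of boundary faces with one boundary condition.

    ``span`` is a pair of half-open index ranges along the two tangential
    axes of the face (ascending axis order), e.g. for a ``+y`` face the
    ranges run over (i, k).
    """

    name: str
    face: str
    kind: PatchKind
    span: tuple[tuple[int, int], tuple[int, int]] | None = None
    inlet_velocity: float = 0.0       # m/s, normal component, >= 0 (into domain)
    inlet_concentration: float = 0.0  # mol/m^3
    pressure: float = 0.0             # Pa, reference for PRESSURE_OUTLET

    def __post_init__(self):
        if self.face not in FACES:
            raise ConfigurationError(f"unknown face {self.face!r}")
        if self.kind == PatchKind.VELOCITY_INLET:
            if not np.isfinite(self.inlet_velocity) or self.inlet_velocity < 0:
                raise ConfigurationError(
                    f"patch {self.name!r}: inlet velocity must be finite and >= 0"
                )


@dataclass
class StructuredGrid:
    """Cartesian control-volume mesh with per-CV material tags."""

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float
    dz: float
    origin: np.ndarray                      # (3,)
    cv_kind: np.ndarray = None              # (nx,ny,nz) of CVKind
    porosity: np.ndarray = None             # (nx,ny,nz), 1 for FLUID
    permeability: np.ndarray = None         # (nx,ny,nz) m^2, inf for FLUID
    patches: list[BoundaryPatch] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 1:
            raise ConfigurationError("CV counts must be >= 1")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ConfigurationError("CV spacings must be > 0")
        self.origin = np.asarray(self.origin, dtype=float)
        shp = self.shape
        if self.cv_kind is None:
            self.cv_kind = np.full(shp, CVKind.FLUID, dtype=np.int8)
        if self.porosity is None:
            self.porosity = np.ones(shp)
        if self.permeability is None:
            self.permeability = np.full(shp, np.inf)
        self._validate_materials()
        self._patch_maps = None  # built lazily

    # -- basic geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def spacing(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz])

    @property
    def extent(self) -> np.ndarray:
        """Edge lengths of the bounding box."""
        return self.spacing * np.array(self.shape)

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.extent

    @property
    def cell_volume(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def is_planar(self) -> bool:
        return self.nz == 1

    def axis_active(self, axis: int) -> bool:
        return self.shape[axis] > 1

    @property
    def ndim_active(self) -> int:
        return sum(self.axis_active(a) for a in range(3))

    def face_area(self, axis: int) -> float:
        d = self.spacing
        return float(np.prod([d[a] for a in range(3) if a != axis]))

    def centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def cell_center(self, idx) -> np.ndarray:
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.spacing

    @property
    def open_mask(self) -> np.ndarray:
        return self.cv_kind != CVKind.BLOCKED

    # -- point location --------------------------------------------------

    def contains(self, position) -> bool:
        p = np.asarray(position, dtype=float)
        return bool(np.all(p >= self.origin - 1e-15) and np.all(p <= self.upper + 1e-15))

    def locate_cv(self, position) -> tuple[int, int, int]:
        """Owning CV of a point under half-open ownership.

        Points exactly on the upper domain boundary map to the last CV.
        """
        p = np.asarray(position, dtype=float)
        if not self.contains(p):
            raise OutOfDomainError(f"position {p} outside domain box")
        idx = np.floor((p - self.origin) / self.spacing).astype(int)
        idx = np.minimum(np.maximum(idx, 0), np.array(self.shape) - 1)
        return tuple(int(v) for v in idx)

    # -- boundary patches -------------------------------------------------

    def attach_patches(self, patches: list[BoundaryPatch]) -> None:
        """Attach patches, filling unspecified span with the full face and
        validating that patches on a face do not overlap."""
        resolved = []
        for p in patches:
            t1, t2 = face_tangent_axes(p.face)
            n1, n2 = self.shape[t1], self.shape[t2]
            span = p.span if p.span is not None else ((0, n1), (0, n2))
            (a0, a1), (b0, b1) = span
            if not (0 <= a0 < a1 <= n1 and 0 <= b0 < b1 <= n2):
                raise ConfigurationError(
                    f"patch {p.name!r} span {span} does not fit on face {p.face} "
                    f"({n1}x{n2} faces)"
                )
            q = BoundaryPatch(p.name, p.face, p.kind, ((a0, a1), (b0, b1)),
                              p.inlet_velocity, p.inlet_concentration, p.pressure)
            resolved.append(q)
        self.patches = resolved
        self._patch_maps = None
        self.patch_maps()  # force overlap validation

    def patch_maps(self) -> dict[str, np.ndarray]:
        """Per-face 2D integer maps: index into ``self.patches`` or -1 (wall)."""
        if self._patch_maps is not None:
            return self._patch_maps
        maps = {}
        for fname in FACES:
            t1, t2 = face_tangent_axes(fname)
            maps[fname] = np.full((self.shape[t1], self.shape[t2]), -1, dtype=int)
        for ip, p in enumerate(self.patches):
            (a0, a1), (b0, b1) = p.span
            m = maps[p.face][a0:a1, b0:b1]
            if np.any(m != -1):
                raise ConfigurationError(
                    f"patch {p.name!r} overlaps another patch on face {p.face}"
                )
            m[:] = ip
        self._patch_maps = maps
        return maps

    def patch_at(self, face: str, t1: int, t2: int) -> BoundaryPatch | None:
        """Patch covering face element (t1, t2), or None for a default wall."""
        ip = self.patch_maps()[face][t1, t2]
        return self.patches[ip] if ip >= 0 else None

    def patches_of_kind(self, kind: PatchKind) -> list[BoundaryPatch]:
        return [p for p in self.patches if p.kind == kind]

    def patch_face_count(self, patch: BoundaryPatch) -> int:
        (a0, a1), (b0, b1) = patch.span
        return (a1 - a0) * (b1 - b0)

    def patch_area(self, patch: BoundaryPatch) -> float:
        axis, _ = FACES[patch.face]
        return self.patch_face_count(patch) * self.face_area(axis)

    # -- validation -------------------------------------------------------

    def _validate_materials(self):
        porous = self.cv_kind == CVKind.POROUS
        fluid = self.cv_kind == CVKind.FLUID
        if np.any((self.porosity[porous] <= 0) | (self.porosity[porous] > 1)):
            raise ConfigurationError("POROUS CVs need 0 < porosity <= 1")
        if np.any(self.permeability[porous] <= 0):
            raise ConfigurationError("POROUS CVs need permeability > 0")
        if np.any(self.porosity[fluid] != 1.0):
            raise ConfigurationError("FLUID CVs must have porosity 1")


def locate_cv(grid: StructuredGrid, position) -> tuple[int, int, int]:
    """Module-level alias of :meth:`StructuredGrid.locate_cv`."""
    return grid.locate_cv(position)


# ---------------------------------------------------------------------------
# Geometry presets
# ---------------------------------------------------------------------------

@dataclass
class GeometryPreset:
    """A named geometry with its dimension parameters and port placements."""

    name: str
    params: dict = field(default_factory=dict)


def _port_span(n: int, fraction: float, flush_high: bool) -> tuple[int, int]:
    w = max(1, int(round(fraction * n)))
    return (n - w, n) if flush_high else (0, w)


def geometry_a(
    resolution=(40, 40, 8),
    *,
    length=1e-3,
    width=1e-3,
    depth=2e-4,
    porosity=0.75,
    permeability=1e-10,
    port_fraction=0.2,
    inlet_velocity=0.001 / 3600.0,
    inlet_concentration=0.21,
    outlet_pressure=0.0,
) -> StructuredGrid:
    """Box bioreactor, inlet port top-left, outlet port bottom-right.

    The box is 1 x 1 x 0.2 mm at full scale and entirely scaffold
    (porosity 0.75, permeability 1e-10 m^2 by default).  Ports are square
    patches covering ``port_fraction`` of the face edge, flush to the
    named corners; the port size is not a measured quantity and can be
    overridden.  The default inlet speed is 2.78e-7 m/s (1 mm/hr of
    medium; see the methods note on the per-hour unit system of the
    device parameters).
    """
    nx, ny, nz = resolution
    grid = StructuredGrid(
        nx, ny, nz, length / nx, width / ny, depth / nz,
        origin=np.zeros(3),
        cv_kind=np.full((nx, ny, nz), CVKind.POROUS, dtype=np.int8),
        porosity=np.full((nx, ny, nz), float(porosity)),
        permeability=np.full((nx, ny, nz), float(permeability)),
    )
    inlet = BoundaryPatch(
        "inlet", "+y", PatchKind.VELOCITY_INLET,
        span=(_port_span(nx, port_fraction, flush_high=False), (0, nz)),
        inlet_velocity=inlet_velocity, inlet_concentration=inlet_concentration,
    )
    outlet = BoundaryPatch(
        "outlet", "-y", PatchKind.PRESSURE_OUTLET,
        span=(_port_span(nx, port_fraction, flush_high=True), (0, nz)),
        pressure=outlet_pressure,
    )
    grid.attach_patches([inlet, outlet])
    grid.meta.update(preset="GEOMETRY_A", scaffold_volume=length * width * depth)
    return grid


def geometry_b(
    resolution=(40, 40, 8),
    *,
    length=1e-3,
    width=1e-3,
    depth=2e-4,
    porosity=0.75,
    permeability=1e-10,
    port_fraction=0.2,
    inlet_velocity=0.001 / 3600.0,
    inlet_concentration=0.21,
    outlet_pressure=0.0,
) -> StructuredGrid:
    """Box bioreactor, inlet port top-right, outlets along the entire left
    and bottom faces.  Same outer box and scaffold as geometry A."""
    nx, ny, nz = resolution
    grid = StructuredGrid(
        nx, ny, nz, length / nx, width / ny, depth / nz,
        origin=np.zeros(3),
        cv_kind=np.full((nx, ny, nz), CVKind.POROUS, dtype=np.int8),
        porosity=np.full((nx, ny, nz), float(porosity)),
        permeability=np.full((nx, ny, nz), float(permeability)),
    )
    inlet = BoundaryPatch(
        "inlet", "+y", PatchKind.VELOCITY_INLET,
        span=(_port_span(nx, port_fraction, flush_high=True), (0, nz)),
        inlet_velocity=inlet_velocity, inlet_concentration=inlet_concentration,
    )
    outlet_left = BoundaryPatch(
        "outlet_left", "-x", PatchKind.PRESSURE_OUTLET, pressure=outlet_pressure,
    )
    outlet_bottom = BoundaryPatch(
        "outlet_bottom", "-y", PatchKind.PRESSURE_OUTLET, pressure=outlet_pressure,
    )
    grid.attach_patches([inlet, outlet_left, outlet_bottom])
    grid.meta.update(preset="GEOMETRY_B", scaffold_volume=length * width * depth)
    return grid


def insall_chamber(
    resolution=(45, 20, 1),
    *,
    outer_well_length=2e-3,
    inner_well_length=2e-3,
    bridge_length=5e-4,
    well_width=2e-3,
    bridge_width=1e-3,
    depth=2e-4,
) -> StructuredGrid:
    """Planar two-well chemotaxis-chamber domain.

    Outer well (chemoattractant reservoir) on the low-x side, inner well
    (control) on the high-x side, connected by a bridge of length
    ``bridge_length`` (0.5 mm, the one printed dimension) and width
    ``bridge_width``.  Solid chamber walls above and below the bridge are
    BLOCKED CVs.  The well extents are configurable defaults, not
    measured values.  Closed domain (all walls); transport is by
    diffusion only.
    """
    nx, ny, nz = resolution
    Lx = outer_well_length + bridge_length + inner_well_length
    grid = StructuredGrid(
        nx, ny, nz, Lx / nx, well_width / ny, depth / max(nz, 1),
        origin=np.zeros(3),
    )
    xc = grid.centers(0)
    yc = grid.centers(1)
    in_bridge_x = (xc >= outer_well_length) & (xc <= outer_well_length + bridge_length)
    off_bridge_y = np.abs(yc - well_width / 2.0) > bridge_width / 2.0
    blocked = in_bridge_x[:, None, None] & off_bridge_y[None, :, None]
    blocked = np.broadcast_to(blocked, grid.shape).copy()
    grid.cv_kind[blocked] = CVKind.BLOCKED
    grid.attach_patches([])
    grid.meta.update(
        preset="INSALL",
        outer_well_length=outer_well_length,
        bridge_length=bridge_length,
        bridge_width=bridge_width,
        well_width=well_width,
        # unit vector pointing toward the attractant (outer) well
        attractant_axis=(-1.0, 0.0, 0.0),
    )
    return grid


def box_2d(
    resolution=(20, 20, 1),
    *,
    length=1e-3,
    width=1e-3,
    depth=2e-4,
    porosity=1.0,
    permeability=None,
) -> StructuredGrid:
    """Closed planar box (all walls), free fluid by default."""
    nx, ny, nz = resolution
    kind = CVKind.FLUID if porosity == 1.0 else CVKind.POROUS
    grid = StructuredGrid(
        nx, ny, nz, length / nx, width / ny, depth / nz,
        origin=np.zeros(3),
        cv_kind=np.full((nx, ny, nz), kind, dtype=np.int8),
        porosity=np.full((nx, ny, nz), float(porosity)),
        permeability=np.full(
            (nx, ny, nz), np.inf if permeability is None else float(permeability)
        ),
    )
    grid.attach_patches([])
    grid.meta.update(preset="BOX_2D")
    return grid


PRESETS: dict[str, Callable[..., StructuredGrid]] = {
    "GEOMETRY_A": geometry_a,
    "GEOMETRY_B": geometry_b,
    "INSALL": insall_chamber,
    "BOX_2D": box_2d,
}


def build_grid(preset, resolution=None, **overrides) -> StructuredGrid:
    """Build a grid from a preset name (or :class:`GeometryPreset`).

    ``resolution`` overrides the preset's per-axis CV counts; any other
    keyword is forwarded to the preset builder.
    """
    if isinstance(preset, GeometryPreset):
        overrides = {**preset.params, **overrides}
        preset = preset.name
    try:
        builder = PRESETS[preset]
    except KeyError:
        raise ConfigurationError(
            f"unknown geometry preset {preset!r}; choose from {sorted(PRESETS)}"
        ) from None
    if resolution is not None:
        resolution = tuple(int(n) for n in resolution)
        if min(resolution) < 1:
            raise ConfigurationError("resolution counts must be >= 1")
        return builder(resolution, **overrides)
    return builder(**overrides)
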