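"""Steady incompressible flow through the bioreactor.

The momentum balance is solved in the Stokes–Brinkman form on a staggered
(MAC) grid: viscous diffusion plus a Darcy resistance ``-(mu/K) u`` in
porous CVs, with the convective term dropped (the Reynolds number of the
perfused devices is far below one for all printed parameters, so the flow
is linear in the inlet speed).  Velocities are superficial
(volume-averaged), which makes face-flux continuity uniform across
fluid/porous interfaces.  The coupled velocity/pressure saddle-point
system is assembled once and solved with a sparse direct factorization;
the converged field conserves mass per CV to machine precision.

Boundary conditions: velocity inlets fix the normal face velocity
(tangential components zero), walls are no-slip, pressure outlets fix the
boundary pressure and leave the outflow profile free (zero normal
gradient).  Axes with a single CV are treated as invariant, so planar
(nz=1) and one-dimensional columns reduce to plane and plug flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, SolverError, WellPosednessError
from .grid_geometry import CVKind, PatchKind, StructuredGrid, face_tangent_axes

__all__ = ["FluidProperties", "FlowState", "solve_steady_flow", "zero_flow"]


@dataclass
class FluidProperties:
    """Culture-medium properties (defaults: water-like medium)."""

    density: float = 1000.0    # kg/m^3
    viscosity: float = 1e-3    # kg/(m s)

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ConfigurationError("density and viscosity must be > 0")


@dataclass
class FlowState:
    """Converged steady flow field for a scenario.

    ``fluxes[d]`` holds the volumetric flow (m^3/s) through every face
    normal to axis ``d`` (shape = grid shape with +1 along ``d``),
    positive in the +axis direction.  ``velocity`` is the superficial
    cell-centered velocity.
    """

    pressure: np.ndarray                 # (nx,ny,nz) Pa
    velocity: np.ndarray                 # (nx,ny,nz,3) m/s
    fluxes: tuple[np.ndarray, np.ndarray, np.ndarray]
    continuity_residual: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def max_speed(self) -> float:
        return float(np.max(np.linalg.norm(self.velocity, axis=-1)))


def zero_flow(grid: StructuredGrid) -> FlowState:
    """A quiescent flow state (used for diffusion-only scenarios)."""
    shp = grid.shape
    fluxes = tuple(
        np.zeros(tuple(n + (1 if a == d else 0) for a, n in enumerate(shp)))
        for d in range(3)
    )
    return FlowState(
        pressure=np.zeros(shp),
        velocity=np.zeros(shp + (3,)),
        fluxes=fluxes,
        continuity_residual=0.0,
    )


def _face_shape(shape, d):
    return tuple(n + (1 if a == d else 0) for a, n in enumerate(shape))


def _boundary_patch_for_face(grid, d, side, midx):
    """Patch governing the boundary face of axis d at ``midx`` (face multi-index)."""
    fname = ("-" if side == 0 else "+") + "xyz"[d]
    t1, t2 = face_tangent_axes(fname)
    return grid.patch_at(fname, midx[t1], midx[t2]), fname


def _classify_faces(grid: StructuredGrid, active):
    """Return per-axis arrays of fixed face velocities (NaN = unknown) and a
    per-axis boolean array marking pressure-outlet boundary faces."""
    shape = grid.shape
    blocked = grid.cv_kind == CVKind.BLOCKED
    fixed = {}
    outlet_face = {}
    n_inlet = 0
    for d in active:
        fshape = _face_shape(shape, d)
        fx = np.full(fshape, np.nan)
        of = np.zeros(fshape, dtype=bool)
        nd = shape[d]
        # interior faces adjacent to a blocked CV carry zero velocity
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[d] = slice(0, nd - 1)
        sl_hi[d] = slice(1, nd)
        face_int = [slice(None)] * 3
        face_int[d] = slice(1, nd)
        adj_blocked = blocked[tuple(sl_lo)] | blocked[tuple(sl_hi)]
        fint = fx[tuple(face_int)]
        fint[adj_blocked] = 0.0
        fx[tuple(face_int)] = fint
        # boundary faces
        for side in (0, 1):
            fi = 0 if side == 0 else nd
            it = np.ndindex(*[fshape[a] if a != d else 1 for a in range(3)])
            for m in it:
                midx = list(m)
                midx[d] = fi
                cell = list(midx)
                cell[d] = 0 if side == 0 else nd - 1
                if blocked[tuple(cell)]:
                    fx[tuple(midx)] = 0.0
                    continue
                patch, _ = _boundary_patch_for_face(grid, d, side, midx)
                if patch is None or patch.kind == PatchKind.WALL:
                    fx[tuple(midx)] = 0.0
                elif patch.kind == PatchKind.VELOCITY_INLET:
                    sgn = 1.0 if side == 0 else -1.0
                    fx[tuple(midx)] = sgn * patch.inlet_velocity
                    n_inlet += 1
                else:  # pressure outlet: velocity unknown
                    of[tuple(midx)] = True
        fixed[d] = fx
        outlet_face[d] = of
    return fixed, outlet_face, n_inlet


def solve_steady_flow(
    grid: StructuredGrid,
    fluid: FluidProperties = None,
    patches=None,
    *,
    tolerance: float = 1e-8,
    max_outer_iterations: int = 1,
) -> FlowState:
    """Solve the steady Stokes–Brinkman equations on ``grid``.

    ``patches`` overrides the grid's attached boundary patches.  The
    system is linear, so a single sparse direct solve converges; the
    continuity residual (max per-CV net flux scaled by the inlet flux) is
    checked against ``tolerance`` and a :class:`SolverError` is raised if
    it is exceeded.
    """
    if fluid is None:
        fluid = FluidProperties()
    if patches is not None:
        grid = _with_patches(grid, patches)

    mu = fluid.viscosity
    shape = grid.shape
    blocked = grid.cv_kind == CVKind.BLOCKED
    open_mask = ~blocked
    dxs = grid.spacing
    active = [d for d in range(3) if grid.axis_active(d)]

    inlets = [p for p in grid.patches_of_kind(PatchKind.VELOCITY_INLET)
              if p.inlet_velocity > 0]
    outlets = grid.patches_of_kind(PatchKind.PRESSURE_OUTLET)
    if inlets and not outlets:
        raise WellPosednessError("velocity inlet specified but no pressure outlet")

    # per-cell Darcy resistance mu/K (zero in free fluid)
    resist = np.zeros(shape)
    porous = grid.cv_kind == CVKind.POROUS
    resist[porous] = mu / grid.permeability[porous]

    fixed, outlet_face, _ = _classify_faces(grid, active)

    # unknown numbering: face velocities per active axis, then pressures
    uidx = {}
    n_unknowns = 0
    for d in active:
        idx = np.full(fixed[d].shape, -1, dtype=np.int64)
        free = np.isnan(fixed[d])
        idx[free] = n_unknowns + np.arange(int(free.sum()))
        n_unknowns += int(free.sum())
        uidx[d] = idx
    pidx = np.full(shape, -1, dtype=np.int64)
    pidx[open_mask] = n_unknowns + np.arange(int(open_mask.sum()))
    n_total = n_unknowns + int(open_mask.sum())

    rows, cols, vals = [], [], []
    rhs = np.zeros(n_total)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    nd_of = dict(zip(range(3), shape))

    # ---- momentum equations -------------------------------------------
    for d in active:
        dd = dxs[d]
        fshape = fixed[d].shape
        fxd = fixed[d]
        idxd = uidx[d]
        nd = shape[d]
        free_faces = np.argwhere(np.isnan(fxd))
        for m in free_faces:
            m = tuple(int(v) for v in m)
            row = idxd[m]
            fi = m[d]
            diag = 0.0
            # viscous Laplacian
            for e in active:
                de = dxs[e]
                coef = mu / (de * de)
                for step in (-1, 1):
                    nb = list(m)
                    nb[e] += step
                    if e == d:
                        if nb[e] < 0 or nb[e] > nd:
                            # beyond an outlet boundary: zero normal gradient
                            continue
                        exists = True
                    else:
                        exists = 0 <= nb[e] <= nd_of[e] - 1
                    if exists:
                        nb = tuple(nb)
                        v = fxd[nb]
                        diag -= coef
                        if np.isnan(v):
                            add(row, idxd[nb], coef)
                        else:
                            rhs[row] -= coef * v
                    else:
                        # tangential ghost beyond the domain boundary
                        side = 0 if nb[e] < 0 else 1
                        bm = list(m)
                        bm[d] = min(fi, nd - 1)  # clamp to a cell index
                        bm[e] = 0 if side == 0 else nd_of[e] - 1
                        patch, _ = _boundary_patch_for_face(grid, e, side, bm)
                        if patch is not None and patch.kind == PatchKind.PRESSURE_OUTLET:
                            pass  # zero-gradient ghost: term cancels
                        else:
                            diag -= 2.0 * coef  # no-slip: ghost = -u
            # Darcy resistance (mean of adjacent open cells)
            rvals = []
            for side, ci in ((0, fi - 1), (1, fi)):
                if 0 <= ci <= nd - 1:
                    cc = list(m)
                    cc[d] = ci
                    if open_mask[tuple(cc)]:
                        rvals.append(resist[tuple(cc)])
            if rvals:
                diag -= float(np.mean(rvals))
            add(row, row, diag)
            # pressure gradient
            cl = list(m)
            cl[d] = fi - 1
            cr = list(m)
            cr[d] = fi
            has_l = fi - 1 >= 0
            has_r = fi <= nd - 1
            if has_l and has_r:
                add(row, pidx[tuple(cl)], 1.0 / dd)
                add(row, pidx[tuple(cr)], -1.0 / dd)
            elif has_l:  # face on the high boundary (outlet)
                patch, _ = _boundary_patch_for_face(grid, d, 1, m)
                add(row, pidx[tuple(cl)], 2.0 / dd)
                rhs[row] += (2.0 / dd) * patch.pressure
            else:        # face on the low boundary (outlet)
                patch, _ = _boundary_patch_for_face(grid, d, 0, m)
                add(row, pidx[tuple(cr)], -2.0 / dd)
                rhs[row] -= (2.0 / dd) * patch.pressure

    # ---- continuity equations -----------------------------------------
    # row scaling keeps the saddle system well-conditioned for the LU
    cscale = (mu / float(np.min(dxs[[d for d in active]])) ** 2) / max(
        grid.face_area(active[0]), 1e-300
    )
    pin_pressure = not outlets
    pinned = False
    for cell in np.argwhere(open_mask):
        cell = tuple(int(v) for v in cell)
        row = pidx[cell]
        if pin_pressure and not pinned:
            add(row, row, 1.0)
            pinned = True
            continue
        for d in active:
            area = grid.face_area(d)
            for side, fi in ((0, cell[d]), (1, cell[d] + 1)):
                fm = list(cell)
                fm[d] = fi
                fm = tuple(fm)
                sgn = -1.0 if side == 0 else 1.0  # outward at +face
                v = fixed[d][fm]
                if np.isnan(v):
                    add(row, uidx[d][fm], sgn * area * cscale)
                else:
                    rhs[row] -= sgn * area * v * cscale

    A = sp.csc_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n_total, n_total))
    )
    try:
        sol = spla.spsolve(A, rhs)
    except Exception as exc:  # pragma: no cover - pathological inputs
        raise SolverError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise SolverError("flow solve produced non-finite values")

    # ---- unpack ---------------------------------------------------------
    fluxes = []
    for d in range(3):
        fshape = _face_shape(shape, d)
        if d in active:
            u = fixed[d].copy()
            free = np.isnan(u)
            u[free] = sol[uidx[d][free]]
            fluxes.append(u * grid.face_area(d))
        else:
            fluxes.append(np.zeros(fshape))
    pressure = np.zeros(shape)
    pressure[open_mask] = sol[pidx[open_mask]]

    velocity = np.zeros(shape + (3,))
    for d in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[d] = slice(0, shape[d])
        hi[d] = slice(1, shape[d] + 1)
        uface = fluxes[d] / grid.face_area(d)
        velocity[..., d] = 0.5 * (uface[tuple(lo)] + uface[tuple(hi)])

    div = np.zeros(shape)
    for d in active:
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[d] = slice(0, shape[d])
        hi[d] = slice(1, shape[d] + 1)
        div += fluxes[d][tuple(hi)] - fluxes[d][tuple(lo)]
    inflow = sum(
        p.inlet_velocity * grid.patch_area(p) for p in inlets
    )
    scale = inflow if inflow > 0 else max(np.max(np.abs(fluxes[active[0]])), 1e-300)
    residual = float(np.max(np.abs(div[open_mask])) / scale)
    if residual > tolerance:
        raise SolverError(
            f"continuity residual {residual:.3e} exceeds tolerance {tolerance:.1e}",
            residuals=[residual],
        )
    return FlowState(
        pressure=pressure,
        velocity=velocity,
        fluxes=tuple(fluxes),
        continuity_residual=residual,
        meta={"inflow": inflow},
    )


def _with_patches(grid: StructuredGrid, patches) -> StructuredGrid:
    import copy

    g = copy.copy(grid)
    g._patch_maps = None
    g.attach_patches(list(patches))
    return g
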