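# Methods

## Model overview

`perfusim` couples a continuum transport solver to an off-lattice agent
population in alternating 15-minute cycles (first-order operator
splitting). Within a cycle the agent positions are frozen while the
scalar field takes one implicit step; the agents then sense the updated
field and move, collide, divide or die. The flow field is solved once
per scenario: the cells act on the species equation only (they are
moving sinks), never on the momentum equation.

### Flow

Steady incompressible flow through the device is modelled in the
Stokes–Brinkman form on a staggered (MAC) finite-volume grid:

    0 = -∇p + µ∇²u - (µ/K) u,   ∇·u = 0

with the Darcy resistance active in porous control volumes (scaffold
porosity ε = 0.75, permeability K = 10⁻¹⁰ m²) and zero in free fluid.
Velocities are superficial (volume-averaged), which keeps face-flux
continuity uniform across fluid/porous interfaces. The convective
momentum term is dropped: for every parameter set shipped with the
package the Reynolds number is far below one, so the flow is linear in
the inlet speed (verified by a test). The coupled velocity/pressure
saddle-point system is solved by a sparse direct factorization; per-CV
continuity then holds to machine precision. Boundary conditions:
velocity inlets fix the normal face velocity with zero tangential slip,
walls are no-slip, pressure outlets fix the boundary pressure and leave
the outflow profile free. Axes with a single CV are treated as
invariant, giving planar (nz = 1) and 1-D reductions.

### Species transport

One scalar is transported per scenario (oxygen in the bioreactors, FBS
in the chamber). The finite-volume discretization integrates

    ∂(εΦ)/∂t + ∇·(uΦ) = ∇·(Γ∇Φ) + S_C + S_P Φ

with backward-Euler time stepping (unconditionally stable; one step per
coupling cycle by default, sub-stepping available). Convection enters
the implicit matrix as first-order upwind plus an explicit
deferred-correction that upgrades the face value to second order:

* `tvd` (default): van Leer limiter; strictly bounded once the
  correction sweeps converge (the sweep cap of 12 is generous — smooth
  coupled fields converge in 2–3), but clips to first order at faces
  with no far-upwind neighbour (domain boundaries) and at extrema.
* `central`: unlimited central differencing; uniformly second order on
  smooth problems (this variant is used for the grid-convergence study)
  but not monotone.
* `upwind`: robust first-order fallback.

Porosity closure: the transient term is scaled by ε (the scalar lives in
the pore space), convection uses the superficial velocity, and the
diffusivity is left unmodified. This is the simplest closure consistent
with treating the scaffold in a Darcian sense; an effective-medium
(tortuosity) correction to Γ would be a one-line change but is not part
of the published parameter set.

Cell consumption is deposited per cycle into the CV owning each live
cell's center at 12.2 mol m⁻³ hr⁻¹ per cell, co-located cells summing.
Where the local concentration is below a cutoff (1 % of the reference
concentration by default) the constant sink switches to the
proportional Patankar form S_P = −rate/cutoff, which guarantees the
implicit solution stays non-negative while consuming "when available".

A mass ledger (inflow, outflow, consumed, storage) is accumulated from
the exact discrete boundary and source expressions, so it closes to
linear-solver precision over any interval — this is asserted for every
scenario in the tests.

Agents sample the field by trilinear interpolation of CV-centered
values (nearest-value extension inside the half-CV boundary margin) and
sense gradients from central-difference CV gradients interpolated the
same way, one-sided at boundaries. Interior-wall (BLOCKED) cells are
filled with neighbour averages before interpolation so sampling near
chamber walls degrades gracefully.

### Cell rules

Parameters (defaults, oxygen-limited phenotype):

| parameter | value | units | role |
|---|---|---|---|
| radius | 10 | µm | non-deformable sphere |
| random-walk speed | 10 | µm/hr | persistent random walk |
| persistence time | 2 | h | direction redraw period (motion time only) |
| chemotaxis speed | 20 | µm/hr | straight up the oxygen gradient |
| chemotaxis/hypoxia threshold | 0.0672 | mol/m³ | below → chemotaxis + hypoxia clock |
| apoptotic marker | 7 | h | continuous hypoxia → flag (kept as history) |
| apoptotic death | 15 | h | continuous hypoxia → death |
| rest period | 1 | h | after contacts and around division |
| cell cycle classes | 18/24/32 | h | probabilities 0.64/0.32/0.04 |
| confluence | 4 | bonds | bond = contact within 5 % of a diameter |
| consumption | 12.2 | mol m⁻³ hr⁻¹ | per cell, in its owning CV |

The MV3 melanoma phenotype used in the chamber inverts the chemotaxis
trigger (committed *above* 10 % of the outer-well FBS loading), moves at
8 µm/hr, does not consume the attractant, and has division and
oxygen-driven apoptosis disabled.

Update order within a cycle: sense → hypoxia clocks → motility →
contact resolution → division, with agents processed in id order and a
dedicated RNG substream per (cycle, agent id) — runs are reproducible
bit-for-bit per seed. Notable semantics:

* The hypoxia clock measures *continuous* time below threshold and
  fully resets on reoxygenation (a rescued cell survives); the 7-h
  apoptotic marker persists as history. Death occurs at 15 h of
  continuous hypoxia; the alternative reading (15 h after the marker,
  22 h total) is available behind `death_from_trigger`.
* Division: a cell whose cycle has elapsed first stops for one rest
  period (the pre-division stationary phase), then — if it has fewer
  than four bonded neighbours and is normoxic — places a daughter one
  diameter away in a uniformly random admissible direction (up to 24
  placement retries, otherwise deferred); parent and daughter rest for
  1 h and draw fresh cycle classes. The 32-h upper class follows the
  published parameter table (the accompanying prose says "thirty").
* Contacts: overlapping live pairs are pushed apart symmetrically to
  exactly one diameter (hard-sphere projection standing in for a
  repulsive-force model whose constants are not published); newly
  contacting cells arrest for 1 h and resume in a fresh random
  direction. Boundary penetration is resolved by projecting the center
  to one radius from the wall. Dead cells are inert: they stop moving,
  consuming and dividing, and are excluded from contact mechanics.
* Contact arrest applies in both walk and chemotaxis modes by default
  (`arrest_on_contact_in_chemo` switches it off for chemotaxing cells).

### Chamber validation

The two-well chamber is a planar closed domain: outer well
(chemoattractant reservoir), inner well, and a connecting bridge whose
0.5 mm length is the one published dimension; the well extents are
parameterized defaults (2 × 2 mm wells, 1 mm bridge width), not measured
values. Transport is diffusion-only (Γ_FBS = 8.705 × 10⁻¹¹ m²/s); the
attractant starts in the outer well at a unit loading and zero
elsewhere, and 20 cells are seeded on the bridge. The validation runs
25 h and repeats the identical run (same seed, same initial positions,
same RNG substreams) without attractant; the per-cell displacements
along the chamber axis, signed toward the attractant well, are compared
with a paired two-tailed Student t test at α = 0.05 (a paired Wilcoxon
alternative is provided). Pairing by matched seed/initial position is
the implemented interpretation of the paired design. Division is
disabled during the 25-h validation window by default.

## Unit system of the device parameters

The published device tables are internally inconsistent: the flow-rate
column does not match the inlet velocities and port areas under any SI
reading, and the inlet speeds printed as m/s would flush the 1 mm
device in about one second — four orders of magnitude more supply than
the largest conceivable population could consume, freezing the oxygen
field at the inlet value forever. The diffusivity is printed per hour
(10⁻⁵ m²/hr). `perfusim`'s scenario presets therefore read the inlet
speeds as per-hour figures (0.001 m/hr = 2.78 × 10⁻⁷ m/s, and 10× that),
the only choice under which the supply is comparable to the consumption
of a growing population and the concentration field can keep evolving
over days. The numerics fixtures (Poiseuille, Darcy) keep plain SI
values; every solver works in SI regardless.

## Reduced-scale study sizes

The full-size device grids (≈100,000 CVs) are supported but the shipped
scenario presets and the test suite run 40 × 40 × 8 reductions of the
1 × 1 × 0.2 mm box, which preserve the transport character (cell Péclet
and the consumption/supply balance change only through the CV volume
entering the per-cell sink). The paired inlet-velocity comparison in
the acceptance suite uses a 48-hour matched time; a full-length (144 h)
Case-3 run is reported in the README example. The chamber validation
runs its full 25 hours on a 45 × 20 planar grid.

## What the synthetic scenarios do and do not show

The simulator's inputs are scenario presets, not measured data. Passing
tests demonstrate that the implemented rule set reproduces its stated
constants exactly, that the transport solvers converge to the analytic
solutions they discretize, and that the coupled system exhibits the
qualitative feedback signature (a seeded reactor never reaches a
stationary field; a cell-free one does). They do not demonstrate
biological fidelity: real cell populations show heterogeneous speeds
and uptake rates, deformable contact mechanics, matrix remodelling and
nutrient co-limitation, none of which are modelled.

A quantitative caveat found while building the acceptance suite: with
the published parameter set (per-cell sink 12.2 mol m⁻³ hr⁻¹,
Γ = 10⁻⁵ m²/hr, supply at 0.21 mol/m³, threshold 0.0672 mol/m³), a
single cell depresses its local oxygen by only ~10⁻⁴ mol/m³, so hypoxia
can arise only when the *population's* total consumption rivals the
device supply. Starting from 5 cells this takes more than the 6-day
horizon of the corresponding scenario (the field bottoms out at
~0.14 mol/m³, still above threshold), so on that horizon the two inlet
velocities support identical growth and the velocity-dependent survival
contrast does not materialize; the corresponding acceptance check
documents this outcome rather than relaxing the parameters. The
hypoxia-driven rules themselves are exercised and verified at rule
level and in the chamber validation.

## Numerical choices and degenerate inputs

* Linear solves: sparse direct LU (SuperLU). The transport operator is
  factored once per (flow, Δt, S_P-pattern) and reused across cycles.
* Flow tolerance: the continuity residual (max per-CV net flux over the
  inlet flux) must be ≤ 10⁻⁸; the direct solve leaves ~10⁻¹⁵.
* All-wall domains pin one pressure DOF; an inlet without any outlet is
  rejected as ill-posed.
* Half-open CV ownership `[lo, hi)` per axis; points on the upper
  domain boundary belong to the last CV.
* Zero gradient during chemotaxis → a uniformly random direction.
* Division placement failure after 24 retries defers to the next cycle.
* Daughters inherit nothing: fresh cycle class, rest clock and
  direction.
* Ports are square patches covering 20 % of their face edge, flush to
  the named corner — the published figures fix the corners but not the
  port sizes; both are overridable in the geometry config.

## Known limitations

* First-order operator splitting between transport and agents (the
  15-minute cycle is the published coupling interval; halving it is a
  config change).
* The limited convection scheme is first order at boundaries and
  extrema; use `central` for smooth-problem convergence studies.
* Dead cells vanish from mechanics rather than persisting as obstacles.
* Interior-wall contact uses CV-resolution geometry (a move ending in a
  wall CV is cancelled), so wall shapes are staircase approximations.
* Single species per scenario; no shear-stress responses, no
  differentiation, no matrix secretion/degradation.
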