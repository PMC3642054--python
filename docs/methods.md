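# Methods

`ramsim` simulates the growth of a two-dimensional longitudinal section of
the *Arabidopsis thaliana* root apical meristem (RAM) as three coupled
dynamics on a Voronoi tessellation: relaxation of an elastic tissue
potential, polar (PIN-gated) auxin transport driven by that potential, and
a per-cell cyclin oscillator, set by local auxin, that triggers divisions.
This note records the model equations as implemented, the parameters that
matter and their defaults, the numerical choices, and the limits of what
the simulations show.

## Tissue geometry

The domain is a rectangle capped below by a parabolic tip
(`y = apex_y + tip_depth (2x/width)^2`), with the apex at the origin and y
growing from tip to base.  Fixed generating points sampled along the
outline at ~`boundary_spacing` intervals represent the epidermal/root-cap
cells; they never move, and their (infinite) Voronoi regions carry no
dynamics.  Mobile interior generators represent meristematic cells; each
cell is the Voronoi region of its generator, computed with a Delaunay
triangulation (scipy) and clipped to the outline where needed (shapely).

The equilibrium cell area is defined globally as `Abar = (domain area) /
(number of interior cells)`.  Every division extends the upper edge of the
domain by exactly `Abar / width`, which keeps `Abar` invariant over the
whole run — the "exact extra space" bookkeeping is exact to floating
round-off, and tests assert it.

Defaults: width 80 µm, tip depth 30 µm, initial rectangle height 10 µm,
boundary spacing 12 µm.  With the standard initial population of 8 random
interior cells plus 2 pinned quiescent-centre (QC) cells this gives
`Abar ≈ 238 µm²` (cell diameter ≈ 16 µm, a realistic meristematic size).

## Elastic field

Each interior cell i contributes a harmonic potential

    V_i = K_v (A_i − Abar)² + K_c |r_i − c_i|²,

the quadratic (leading-order) expansion of any wall-elasticity energy
around the uniform hexagonal packing: the first term penalizes wrong cell
size, the second wrong shape (in a relaxed packing the generating point
r_i and the polygon centroid c_i coincide).  Forces are the exact negative
gradient of `Σ V_i` with respect to the mobile generators.  The gradient
of the Voronoi geometry is evaluated analytically from first-order edge
integrals: when a generator moves, each of its walls (perpendicular
bisectors) slides with a normal velocity proportional to `(z − r_i)·u/d`,
giving per-edge area derivatives `L (m − r_i)/d` and first-moment
derivatives `S/d` with `S = ∮ z (z − r_i)ᵀ ds` (3-point Simpson, exact for
straight walls).  Walls lying on the fixed outline contribute nothing.  A
central-difference oracle in the test suite pins the assembly to ≤1e-4
relative error (observed ~1e-7).

Dynamics are Newtonian with unit cell mass and friction λ,

    dv/dt = F − λ v,    dr/dt = v,

integrated with a semi-implicit Euler step (velocity first, then position
with the new velocity; chosen over the fully explicit variant for
stability at the same cost).  Boundary generators are fixed; a mobile
generator that would cross the rigid outline in one step instead stays put
and loses its velocity.  Generators squeezed below the degeneracy
separation ε = 1e-3·√Abar (possible in crowded post-division clusters) are
nudged apart to 1.5 ε.

Defaults (model units): K_c = 4, K_v = K_c/(12 d²) ≈ 1.2e-3 with d the
equilibrium centroid spacing (so both terms act at comparable magnitude
after a division), λ = 0.25, dt = 0.05 with the stability bound
dt ≤ 0.1·min(1/λ, 1/√K_c) enforced by a warning.  The stiffness-to-friction
ratio K_c/λ sets how fast space added at the growing upper edge propagates
down to the crowded tip, and is part of the growth-rate calibration below.  `mechanics.calibrate` reproduces the
biophysical derivation of these constants: K_c from matching the restoring
force of a cell wall of Young's modulus E strained by the post-division
contraction (areas halve, lengths shrink by √2) against the model force
K_c|r−c| at the daughter offset d/8, giving K_c = 8Eh(1−1/√2)/√3 (linear
in E); λ as the smallest friction that damps oscillation amplitude by a
factor f (default 10) within one period, λ = 2 ln f / T.

## Auxin transport

Auxin is a per-cell dimensionless concentration, rescaled by its maximum
every step (so max C = 1 always; the rescale is the model's implicit
source/sink).  Transport across the wall between adjacent cells i, j is
active and gated: the binary PIN gates decide the *direction* of the flux
— possibly against both the potential and the concentration gradient —
while the magnitude of the elastic-potential difference across the wall
sets its *rate*,

    flux(i→j) = D · L_ij · |V_i − V_j|     gate i→j open only,
    flux(i→j) = D · L_ij · (V_i − V_j)     both directions open (Darcy limit),

plus an ungated, PIN-independent diffusive term `fickian_D · L_ij (C_i −
C_j)` representing plasmodesmatal (symplastic) permeation.  The
direction-from-gates form matters dynamically: if flux only ever ran down
the potential, a freshly divided cell (a local potential spike) could only
export auxin, piling it onto its neighbors and closing a runaway
division→auxin→division loop; with gate-directed pumping the spike is a
through-station and the feedback is negative.  Exchange is
exactly antisymmetric; with rescaling disabled total auxin is conserved to
round-off (tested at 1e-10/step).  A positivity limiter caps each cell's
total efflux per step at its current content, so concentrations cannot go
negative; any deeper negativity aborts the run as a mass-balance bug.

The gates are the binary stand-in for polar PIN efflux carriers
(reverse-fountain rule set): between inner cells only the apexward gate is
open; between two surface cells (cells touching the epidermis) only the
baseward gate; below the QC both directions open (lateral redistribution).
With all gates forced open (`pin off`, the knockout experiment) the law
reduces to plain down-gradient permeation and the apical-basal gradient
collapses; with the rules on, the maximum stays at the QC and the binned
profile decays monotonically toward the base — both are asserted by tests.

Two deliberate design choices differ from the most literal reading of the
source model and are worth recording.  (1) Transport is driven by the raw
per-cell potential, not by V normalized to its maximum: a single large
freshly created cell at the growing edge dominates max V, and normalizing
by it crushes every other potential difference, making transport
diffusion-dominated and destroying the gradient.  Max-normalized V remains
the plotting convention.  (2) The diffusive term defaults on
(`fickian_D > 0`): with purely gated potential-driven flux there is no
mechanism that spreads auxin baseward from the tip maximum, and the
profile collapses to a spike.  Both choices are config switches.

The QC cells start at the maximum and are re-clamped to 1 after each
rescale by default (`qc_clamp`), making the niche an implicit source.

## Cell cycle and division

Each cell runs the adimensional two-species Lotka-Volterra oscillator

    du/dt = u (1 − v),    dv/dt = α v (u − 1)

with u the activator (CYCD role) and v the inhibitor (CYCB role); maxima
of u precede maxima of v as in the G1/S → G2/M succession.  The
small-amplitude period is T_c = 2π/√α, so the clock rate scales as √α.
Auxin couples in linearly, α = a·C + b with a < 0: the cycle slows as
auxin rises (stem cells near the QC cycle slowly), and outside an arrest
window [arrest_below, arrest_above] = [0.15, 0.85] the cycle stops
entirely — auxin starvation far from the tip and auxin excess at the niche
both arrest.  The default map anchors the period at 10.5 h at the arrest
floor and 16 h at the ceiling, which puts the canonical ~12 h period at
the mean auxin level of the actively cycling population (C ≈ 0.44 in
calibrated runs).  Division triggers on an iteration-count threshold: a
cell divides when its clock has accumulated `m_theta · T_c(α)` iterations
since its last reset (m_theta = 0.5) *and* its polygon has regrown to at
least `min_area_frac` (0.15) of the equilibrium area — daughters must
approach adult size before cycling again.  The size gate is the spatial
half of the proliferation control: it converts division into a
space-limited process, so the production rate of the meristem is bounded
by how fast the elastic field delivers area to the tip, which removes the
runaway branch of the coupled dynamics.

The division procedure replaces the mother generator with two points
placed symmetrically along a uniform-random axis at a quarter of the
effective cell radius √(A/π); the mother's kinetic energy is split equally
(velocities along ± the division axis); daughters inherit the mother's
auxin; clocks reset to zero; the domain is extended by exactly Abar.
Quiescent cells reproduce at a rate ten times lower than the others:
their division threshold is `qc_factor` (10) times the median threshold of
the currently cycling ordinary cells.  (Their own auxin is pinned at the
maximum, so a threshold computed from their own α would confound the
tenfold factor with the auxin dependence of the period; the niche is also
exempt from auxin arrest and from the size gate, since a dividing QC keeps
its pinned mother point and sheds one ordinary daughter, leaving the
number and position of the quiescent cells invariant.)

The Euler integrator for the clock (explicit, matching the loop's overall
scheme) preserves the LV first integral `α(u − ln u) + (v − ln v)` to
<0.5% per period at the default small step (dt_c = 1e-3 in the oscillator
tests); inside the engine the oscillator state is advanced with 4
substeps per iteration and the division trigger uses the closed-form
period, so integrator drift cannot bias division timing.

## Time calibration and parameter fitting

One loop iteration represents `days·1440/target_iterations` minutes of
development; the standard calibration is seven days over 3400 iterations
(≈2.96 min/iteration).  The remaining free constants — the transport
rates D (1e-4) and fickian_D (2.5e-3), the division threshold multiplier
m_theta, the arrest window, the size-gate fraction and the
stiffness/friction pair — were fitted, as the model prescribes, so that
the calibrated run grows from 10 cells to a meristem of ≈350 cells in
3400 iterations while maintaining the apical-basal gradient; this fitting
is part of the model's definition, not of any test.  Far from the fitted
point the coupled dynamics are bistable between auxin starvation (the
profile collapses onto the niche and everything arrests) and crowded
runaway growth; the size gate removes the runaway branch and the arrest
window keeps the actively cycling population confined to the annulus
where the profile crosses it.

The stationary meristem length is estimated from the division event log
as the smallest distance from the tip containing 90% of the last-quarter
division events; the literal maximum is exposed as an option but is
dominated by the occasional stray division pocket stranded in the
elongation zone.  Across a decade of the transport constant
(D ∈ [5e-5, 4.6e-4]) the estimated meristem length falls monotonically
and is well fit by a power law; beyond that range the trend reverses
because strong pumping re-activates cells at the growing edge.

## What the simulations do and do not show

The synthetic initial condition and domain emulate the geometry and
initial cellularity of the root tip, not its anatomy: there are no cell
files, no differentiated tissues, no root cap, and PIN polarity is a fixed
rule set rather than an expressed, auxin-regulated protein field.  Passing
tests therefore demonstrate the internal consistency of the coupled model
and its emergent patterning (proliferation confined to a stationary
meristem length, unimodal cell-size distribution, elongation beyond the
meristem), not quantitative agreement with any particular root beyond the
calibration anchors above.  Velocity and rate profiles are reported
against distance from the QC by shifting the tip-based coordinate at
reporting time only.

Two artifacts of the calibrated regime are worth knowing.  First, the
domain's upper edge advances faster than the relaxation flow can carry
cells into the new space, so the last row of cells is strongly stretched
and the occupied cell column (≈450 µm of generators after seven days)
trails the outline (≈1000 µm); axial profiles should therefore be read
against the cell-column extent, not the outline.  Second, the surface
return stream keeps a weak pocket of division activity alive at the
growing edge (typically under 10% of late events); the proliferation
histogram is dominated by the tip zone, and the transition/elongation
midsection is division-free, but the literal "zero events beyond a fixed
distance" holds only up to this edge pocket.  The robust meristem-length
estimator is defined to ignore it.

## Numerical edge cases

Coincident generators (separation < ε) abort tessellation with the pair
named; the engine prevents them as described.  Division offsets shrink
(halving, floored at 1.5 ε) when a daughter would leave the domain or
violate ε.  Ties in the apexward/baseward gate comparison (|Δy| below
1e-6·√Abar) leave gates closed.  Concentrations are clipped at zero before
rescaling.  Re-tessellation happens every step; energy bookkeeping
(V + kinetic) is non-increasing along relaxations up to re-tessellation
jumps bounded at 1% per step in the tests.
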