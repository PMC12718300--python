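# Methods

## The decomposition

For a demographic group α on a gridded domain, the population-weighted
mean exposure is PWM_α = Σᵢ Pᵢ,α Cᵢ / Σᵢ Pᵢ,α, the exposure averaged
over people rather than area. Define

- absolute disparity D_A = PWM_α − PWM_T (concentration units; T the
  total population),
- relative disparity D_R = (PWM_α − PWM_T) / PWM_T (decimal),
- exposure factor XF̄ = PWM_T / E (concentration per unit emission
  rate).

Then D_A = E · XF̄ · D_R is an algebraic identity:
E · (PWM_T/E) · ((PWM_α − PWM_T)/PWM_T) = PWM_α − PWM_T. It therefore
holds in any consistent unit system — the framework functions are
unit-agnostic, and XF̄ absorbs the reciprocal of whatever emission-rate
unit the caller supplies (the simulator uses g/s). D_R is stored in
decimal form and rendered as a percentage only in reports. Negative D_R
(an under-exposed group) is permitted throughout. A corollary used as a
test invariant: over an exhaustive partition into groups, the
population-share-weighted sum of group absolute disparities is zero,
because PWM_T is the share-weighted mean of the group PWMs.

Identity checks in the test suite use 1×10⁻¹² relative tolerance, and
the change-decomposition round trip 1×10⁻¹⁰ — pure floating-point
algebra with no iterative solves. Degenerate inputs are rejected rather
than silently patched: a zero total population makes the PWM undefined
(domain error), zero total exposure makes D_R undefined, zero emissions
make XF̄ undefined, and a zero baseline component makes a fractional
change undefined (the error names the offending component).

Percent changes are signed, 100·(end − start)/start: a relative
disparity moving from 0.1 to 0.12 is reported as +20%. Readers sometimes
describe such a move by the magnitude of its effect instead; reports
therefore carry a separate |change| column, and the sign is never
flipped internally.

## The illustrative city

The city is a deterministic n×n grid (default n = 200) with two
demographic groups:

- total density T(r) = peak · max(0, 1 − r/r_max), with r the Euclidean
  distance from the grid center, peak = 100 persons/cell and
  r_max = n/√2 (the corners are just empty). This is the simplest form
  with a central peak and radial decay.
- group-α share f(x) = x/(n−1) along the west→east axis, so
  pop_α = T·f and pop_β = T·(1−f). The share is antisymmetric about the
  center column while T is mirror-symmetric, so the two group totals are
  equal exactly (to rounding), and the column-wise α fraction rises
  linearly from 0 in the west to 1 in the east.

Coordinates are 0-based, (x, y) = (column from west, row from south);
arrays are indexed [y, x]. Sources may occupy continuous positions; the
field is always evaluated at integer cell coordinates.

## The dispersion model

A single source at (x₀, y₀) with emission rate E produces

    C(x, y) = E/(n·u·H) · exp(−[(x−x₀)² + (y−y₀)²] / (2σ²)),

a radially symmetric Gaussian — a deliberately minimal stand-in for
dispersion, not a downwind plume model. Defaults: u = 5 m/s,
H = 100 m, σ = 40 cells. σ is a model choice: at 20% of the domain the
plume is wide enough that both groups are measurably exposed and narrow
enough that siting creates a disparity. The prefactor uses the grid
*side length* n, not the cell count n²; a `normalization="cells"` switch
substitutes n² for users who prefer a per-cell reading, but the default
follows the side-length form and nothing downstream depends on the
choice (it cancels from XF̄-normalized quantities and scales all
concentrations equally).

The optional first-order loss multiplies each cell by exp(−k·d/u), d the
Euclidean distance from the source in meters (cell distance ×
cell_length, default 100 m/cell — the grid itself is scale-free, the
length enters only here). When enabled without an explicit rate the
default k = u/(50·cell_length) gives an e-folding distance of 50 cells,
a quarter of the domain, so the loss competes visibly with dilution.

Because the field is linear in E, XF̄ and D_R computed from it are
invariant to the emission level; this is the mechanism that freezes the
relative disparity in the fixed-source scenario and it is asserted as a
property test.

## Scenarios

All pathways reduce emissions linearly, E_t = E₀(1 − t/T), over T = 1000
steps from E₀ = 10 g/s. The final step sits one increment (E₀/T) above
zero: "approximately zero" without the 0/0 that an exactly zero field
would create in XF̄. The default source start is (150, 100), inside the
α-dominated east side at the city's mid-latitude.

1. **reduce_E** — constant source position. D_R is constant and
   D_A(f) = (1−f)·D_A(0) exactly.
2. **reduce_E_XF** — the source translates due north (perpendicular to
   the demographic gradient) in equal per-step increments, ending after
   a displacement of n/2 − margin cells. XF̄ falls as the source leaves
   the dense center; the east-side bias, and hence D_R, persists.
3. **reduce_E_XF_DR** — phase 1 (the first T/2 steps) moves the source
   on a straight diagonal, west toward the equity longitude and north
   away from the dense center by the same magnitude, so the exposure
   factor does not rise while the relative disparity falls; D_R crosses
   zero at the trajectory midpoint. Phase 2 continues radially away from
   the center (to a final distance of n/2 − margin cells), reducing XF̄
   further while D_R stays at zero.

Design choices in the trajectories:

- The *equity longitude* — the source x at which D_R,α = 0 — is found by
  bisection at the starting latitude, narrowing the bracket to 10⁻⁶
  cells and requiring |D_R| ≤ 10⁻³ at the result. For the symmetric
  default city it is the center column, at any latitude, by mirror
  symmetry.
- Phase 1 of scenario 3 moves *diagonally*, not due west: a pure
  westward move from (150, 100) would approach the dense center and
  *raise* the exposure factor, which would contradict the scenario's
  defining behavior. The 45° angle is the simplest direction that moves
  away from both the overburdened group and the bulk of the population.
- The endpoint clearance (margin = 25 cells, n/8) keeps the final source
  position more than half a plume standard deviation inside the domain,
  so the Gaussian mass and the population-weighted integrals are not
  badly truncated at the boundary.
- Displacement magnitudes are otherwise free parameters of the toy
  model; they are configurable, and the headline comparison below is
  sensitive to them.

Nothing in the simulator is stochastic: identical configurations produce
byte-identical result files (floats are written with their shortest
round-trip representation for exactly this reason).

## Summary statistics

- `summarize_at_fraction` reports the signed percent change of each
  component between step 0 and the first step at which the
  emission-reduction fraction reaches the requested value (with T = 1000
  the 50% point is exact).
- `emission_reduction_at_zero_disparity` returns the first fraction at
  which |D_A| falls within a tolerance of zero — default one part in 10³
  of its initial magnitude — or 1.0 if that only happens at the final
  step, i.e. if the disparity vanishes only because emissions do.
- `compare_scenarios` reports 100·(r_a − r_b)/r_a, the relative saving
  in required emission reduction.

Under the default configuration the fixed-source and due-north pathways
both return 1.0 (the spatial bias never resolves before emissions are
gone) while the equity pathway eliminates the disparity at fraction
≈ 0.499 — by construction near the midpoint, where D_R crosses zero — a
saving of ≈ 50% relative to emission cuts alone. With the phase-1
duration a free choice, this figure should be read as "roughly half the
emission reduction", not as a sharp constant; steeper equity targeting
(shorter phase 1) raises it, gentler targeting lowers it.

## What the toy model does and does not show

The simulator demonstrates *mechanisms*: which combinations of levers
can eliminate disparities and how fast, with every influence visible and
deterministic. It omits meteorology (no wind direction or downwind
plume), chemistry beyond a single first-order loss, multiple or
heterogeneous sources, microenvironmental and mobility-based exposure
differences, and any calibration to a real city. Passing tests establish
the internal consistency of the decomposition and the qualitative
ordering of the policy archetypes — including robustness to the loss
term — not quantitative predictions for any real population. Applying
the framework to real policies requires replacing the toy field with
modeled or observationally constrained exposure surfaces; the
`decompose` path (and CLI command) accepts arbitrary gridded rasters for
exactly that use.

## Problem sizes used in tests

Unit tests run on shrunken grids (n = 21, T = 50; fixture cities down to
n = 3) where every qualitative property of the full model already holds.
The end-to-end checks and the acceptance script use the full standard
conditions: n = 200, T = 1000, six scenario runs (three pathways, with
and without the loss term), each a second or two of compute.
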