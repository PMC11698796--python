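# Methods

## Model

Two identical elliptic cells of area π (after non-dimensionalisation) move
in the plane.  Cell 1 has centre `(x, y)`, orientation `α` and aspect ratio
`r`; cell 2 is constrained to be its mirror image in the x-axis.  Material
points are `X + s R(α) k(r, θ)` with `s ∈ [0,1]`, rotation matrix `R`, and
shape vector `k = (√r cos θ, sin θ/√r)`, so `r` deforms the cell at fixed
area.  The pair's motion minimises a potential combining substrate
friction, self-propulsion along the orientation, a soft overlap penalty
built from the boundary-intersection points, and relaxation of `r` to a
preferred value `r̄`.  Three non-dimensional groups remain:

| parameter | meaning | typical values used here |
|---|---|---|
| `ν ≥ 0` | self-propulsion speed relative to overlap-avoidance strength (per unit friction) | 0–8; phase portraits at 2 |
| `γ ≥ 0` | overlap avoidance relative to shape restoration; `γ = 0` is the rigid limit | 0, 0.01–1 |
| `r̄ > 0` | preferred aspect ratio; `> 1` long cells, `< 1` wide cells | 1.2–8, mostly 2 |

The mirror symmetry makes the boundary-intersection problem quadratic: the
boundaries cross in 0, 2 or 4 points (regions A, B, C), located in closed
form, and `(α, y, r)` obeys an explicit piecewise-smooth ODE system.  `x`
decouples (`ẋ = ν cos α`) and is carried along for completeness.

Region-C shape change: the governing equations' printed composite form for
`ṙ` in region C (assembled from `α̇` and the overlap part of `ẏ`) is
implemented as such.  It is *not* identical to re-evaluating the generic
`Σ sin 2θ` pair-sum at the region-C intersection points, whereas `ẏ` and
`α̇` are (the test suite checks the pair-sum equivalence for `ẏ, α̇` in all
regions and for `ṙ` in region B).  No analysis result here depends on
region-C shape change — the stability analysis lives on the A-B boundary
and the phase-plane analyses freeze `r` — but users of the full mode should
be aware that region-C `ṙ` follows the composite form.

## Numerical integration

The right-hand side is continuous across both region boundaries (the
region-B square root vanishes on Γ_AB; the B and C branches agree on Γ_BC)
but not differentiable, so trajectories are integrated per region with
`scipy.integrate.solve_ivp` and terminal events on the squared boundary
functions `y² − Γ²`, restarting with the new branch at each resolved root.
Non-obvious choices, all of which were forced by observed failure modes of
the plain approach:

- **Stiff solver (BDF), rtol 1e−9 / atol 1e−11 by default.**  Trajectories
  attracted to the half-stable point slide along the A-B boundary with
  overlap gap `g = γ₁² − y²` of order `α²`; the `√g` term then has a state
  Jacobian of order `1/√g`, and LSODA's finite-difference Jacobian loses
  all digits to the cancellation `y² − γ₁²`, collapsing its steps.  BDF's
  grouped difference scheme copes; analytic Jacobians were not needed.
- **Per-segment local time.**  The system is autonomous; each segment is
  integrated from `t = 0` and times are offset afterwards, because solver
  step-size heuristics degrade when a segment starts at a large absolute
  time.
- **Event hysteresis band (1e−6 on `y² − Γ²`).**  Leave-region events fire
  slightly *inside* the neighbouring region.  Grazing trajectories (the
  alignment funnel touches the A-B boundary repeatedly at the level of
  solver noise) otherwise either chatter or are mis-routed.  Because the
  RHS is continuous across the boundary, detecting the switch a band late
  changes nothing dynamically.
- **Region decided by sign, not by toggling.**  After an event the state is
  nudged one explicit-Euler microstep (1e−9) along the continuous RHS and
  the new region is read off the sign of the boundary function; a tangency
  defaults to the overlapping side.
- **Radicand clamp (1e−13).**  On the A-B boundary `γ₁² − y²` is zero only
  up to rounding; radicands below the clamp evaluate to exactly zero so the
  aligned steady states have exactly vanishing RHS.  More negative
  radicands while classified as overlapping raise an internal-consistency
  error.
- **Termination policy.**  ν = 0 runs stop when the gap event
  `γ₁² − y² = 1e−12` fires (the boundary itself is a quadratic-tangency
  double root no event solver can bracket; the band costs ~1e−5 in the
  arrival time, below the closed-form comparison tolerance).  ν > 0 runs
  stop either when separating in region A (`sign(y) sin α > 0`: straight-
  line motion can never re-enter overlap) or when `α` drops below
  `tol_align = 1e−4`, the operational stand-in for alignment that is only
  reached in infinite time.  Both are configurable.

The large `S_align` sweeps use rtol 1e−7 / atol 1e−9: only the O(1)
terminal angle is needed, and the funnel is strongly contracting.

## Zero-propulsion closed forms

In region B the flow has the explicit first integral

    y² − K(r) log( (cos α)^{r²} / sin α ),   K = (r²+1) / (2r(r²−1)),

giving the trajectory curve `y(α)`, the terminal angle as the unique root
of a strictly increasing function `h(s)` of `s = sin α` (monotonicity is
asserted on a grid before every solve), and the arrival time as an
integral with an inverse-square-root endpoint singularity, removed by the
substitution `u = √(α − α_T)` before adaptive quadrature (tolerance
1e−10).  The right-hand side of the terminal-angle equation carries
`r·y₀²` in the exponent — the form consistent with the trajectory curve by
direct substitution — and the arrival time is `T = I(α_T)(r²+1)/(8(r²−1))`
from separation of variables; both are validated against the integrator's
event times in the test suite (1e−6 on the angle, better than 1e−4 relative
on the time).  The companion monotone-root computation at a B-C boundary
start returns the start itself, the quantitative form of region-B
invariance (a trajectory that enters B never re-enters C).

## Asymptotics near perfect alignment

With perturbation scalings `α = εA`, `y = −1/√r̄ + ε²B`, `r = r̄ + ε²C` and
the distinguished limit `γ = εΓ`, the early layer (`τ = t/ε`) freezes `A`
and drives `(B, C)` to explicit far-field constants; the late layer
(`T = εt`) is an algebraic-decay DAE solved in closed form; the additive
composite subtracts the common part.  `B̂, Ĉ` have no closed form and are
obtained by numerically integrating the early-time system to `τ_max`
(default 10³, by which point they have converged to the far field; beyond
it the constants are used).  Composite accuracy is assessed by
self-convergence — halving ε at fixed Γ contracts the sup-error by ≥ 1.8
(measured ≈ 5 at ε = 0.1 → 0.05) — rather than a fixed tolerance, since the
expansion carries unknown O(1) constants.  The composite orientation
involves only the late layer, hence is exactly independent of Γ.

A technical note on the early-time overlap indicator
`D = (r̄²−1)A² + 2√r̄ B − C/r̄`: its time derivative along the early-time
system carries `+ k C / r̄` (restoring `C` towards zero *increases* `D`),
as the chain rule requires and as the tests check by finite differences.

For slow cells (`ν ≪ 1`) the leading dynamics after the fast ν = 0
transient are confined to the A-B boundary; the reduced single ODE in
`s₀ = sin α` is strictly negative on (0, 1), and its separated time
integral diverges like `(r²+1)/(4√r (r²−1) s₀)` — perfect alignment takes
infinite time.  The fast arrival time used to anchor the slow clock
`τ = ν(t − T)` is the ν = 0 closed-form arrival time.

## Alignment statistic and separatrix

`S_align` is discretised by the midpoint rule on a uniform `n × n` grid
(default 20), which for the discontinuous integrand (the separatrix cuts
the grid) converges at O(1/n); the refinement check doubles `n` and
requires the change to stay below that estimate (measured change ≈ 5e−4 at
20 → 40).  Region-A initial conditions are included (literal reading of the
integral): with `ν > 0` they drift into overlap, and with `ν = 0` they are
stationary and keep `α₀`.  Nodes that hit the time cap (default 10⁴) are
flagged in the map's `coverage` rather than silently dropped; they occur
for slowly-decaying funnel trajectories and carry a near-final angle.

The `ν`-dependence of `S_align` at `r = 2` is non-monotone with `ν = 0`
sub-optimal.  The `r`-dependence is non-monotone with an interior optimum
for `ν ≳ 4`; at `ν = 2` it is monotone decreasing on `r ∈ [1.2, 8]` —
round cells are expelled from deep overlap so strongly (the region-C push
scales like `1/(r²−1)`) that escape is rare and nearly everything aligns.
The bundled sweeps report both.

The separatrix is located per α-slice by bisection on the forward outcome
(aligned below, separated above, to 1e−4 in `y` by default), bracketed
where possible by a backward-time trace seeded near the half-stable point.
Backward integration through the contracting funnel is exponentially
ill-conditioned, so the bisection — not the trace — carries the accuracy.

## What the built-in experiments do and do not show

All quantitative checks run on simulated trajectories of this model with
deterministic, seeded initial-condition fixtures (uniform or
region-stratified over the analysis quadrant).  They validate internal
consistency (closed forms vs. integrator, asymptotics vs. full solutions,
basin geometry vs. trajectory outcomes) at the stated tolerances.  They do
not validate the model against biological data: real cells deform
non-elliptically, interact with more than one neighbour, exert adhesive
forces and experience noise, none of which is represented here.  The
mirror symmetry restricts "alignment" to velocity alignment; nematic
(antiparallel) order cannot occur in this configuration.

## Known limitations

- Orientation analyses assume long cells; `r̄ < 1` is supported by the
  integrator and the stability probe (the head-to-head turning route) but
  the closed forms and alignment statistics require `r > 1`.
- `r = 1` exactly is rejected in overlap regions (no torque; `(r²−1)`
  denominators).
- Backward integration can terminate with a diagnostic error when the
  reversed flow reaches the singular deep-overlap corner `(α, y) → (0,0)`.
- Trajectory times near an event are resolved to the solver's root
  tolerance, but stored region labels within the 1e−6 hysteresis band may
  disagree with the classifier by design.
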