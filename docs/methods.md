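# Methods

## The model

P point agents live on the square `[0, L]^2` (they stop at the boundary;
in the regimes studied here they never reach it, and a test asserts that
runs at the standard parameters produce no wall contacts for sampled
states).  Time advances in sweeps: one sweep (one time unit) consists of P
elementary updates, each performed on an agent drawn uniformly at random
*with replacement* and acting on the positions left by all previous
updates (random-sequential asynchronous dynamics; a random-permutation
selection mode is available via `SimulationParams(selection="permutation")`
for sensitivity checks).

An elementary update of agent i:

1. A gaze direction is drawn uniformly on `[0, 2π)`.  The attention field
   is the closed angular sector of amplitude α bisected by the gaze.
2. The nearest neighbour j inside the sector is found (ties resolve to
   the lowest index; an empty sector means no move this update).  With
   α = 2π this reduces to the global nearest neighbour — Hamilton's
   original selfish-herd movement rule.
3. Let d = |x_j − x_i| and D the stress-zone radius, which doubles as the
   ideal inter-individual distance.  If d > D the agent steps a distance v
   toward j; if the step would enter the stress zone it stops exactly
   where its path crosses the circle of radius D around j.  If d < D it
   steps v directly away from j, stopping at D if it would overshoot.  If
   d = D (within 10⁻¹²) it does not move.
4. Direction noise of strength η ∈ [0, 1] rotates the movement direction
   by an angle uniform on `[−ηπ, +ηπ]` before the step; the stop-at-D rule
   is applied along the noisy path (the agent halts where the path crosses
   the D-circle), so η = 0 is the deterministic rule and η = 1 a fully
   random direction.  This parametrisation of the noise interval, the
   exact step equations and the quiescence-window length are
   reconstructions from the published prose: the printed equations and
   numbers are not recoverable from the text available to us.

A run is *quasi-stationary* after `qs_window` (default 100) consecutive
sweeps with no position change; `t_conv` is the sweep of the last
movement.  Runs that do not reach quiescence within `max_sweeps` are
reported as non-converged — a legitimate outcome, never an error.

### Quasi-stationary versus absorbing states

A quasi-stationary state need not be a strict absorbing state.
`core.movable_agents` decides absorption exactly: agent i can move iff
some gaze direction selects a target at distance ≠ D, which reduces to an
arc-coverage computation (the arcs of gazes won by nearer agents may or
may not cover the arc in which a mis-spaced agent is selectable).  Two
structural facts emerge from this test and shape the phase diagram:

- A perfect triangular lattice with spacing D is a fixed point of the
  noiseless dynamics only for α ≥ π/3.  A narrower sector can frame a
  second-shell neighbour (distance √3·D) while hiding both flanking
  first-shell neighbours, so the crystal is unstable — this is the
  geometric origin of the dense disordered phase at small α, in which
  stress zones are chronically violated and quiescence is never reached.
- Quasi-stationary crystals at intermediate α typically retain a few rim
  agents that *could* move for rare gaze windows; their per-sweep movement
  probability is small enough to pass the quiescence window.  These are
  the "improbable movements remain feasible" states: every agent's first
  metric neighbour sits at exactly D, and the interior Ψ6 equals 1.

`core.is_absorbing` implements the stricter topological criterion (every
Delaunay-neighbour pair at distance D).  Note that for a compact swarm
whose outline has shallow concavities, hull-spanning Delaunay edges exceed
D even when the packing is perfect, so simulated quasi-stationary crystals
generally fail this strict test while passing the exact dynamical one;
the strict version is kept for constructed lattice configurations.

## Order parameters and domains of danger

**Topological neighbours.** Two agents are topological neighbours when
their Voronoi polygons share an edge of positive length.  Bounded cells
are built by mirroring the points across the four sides of the clip
region's bounding box (slightly padded so a point exactly on the boundary
never coincides with its mirror image), taking the scipy Voronoi
tessellation of the 5n points and clipping the first-n cells with shapely.
Cells therefore partition the clip region exactly, and areas sum to its
area to machine precision.

**Ψ6.** Per agent, ψ6(i) is the mean of `exp(6iθ_ij)` over topological
neighbours, θ_ij the bond angle against the positive x-axis (the reference
axis is irrelevant: the modulus of the agent-averaged ψ6 is invariant
under global rotation and translation).  Ψ6 = 1 exactly on a perfect
triangular lattice and ≈ 0.05 for uniform random points.  Two rim
conventions are provided: `interior_only=False` (default) averages all
agents with box-clipped cells; `interior_only=True` excludes agents whose
cell touches the clip-region boundary, whose bond counts the clipping
distorts.  Crystal-phase checks use the interior convention; sweeps use
the all-agents convention for comparability across α.  Whether the
original analysis included rim agents is not recoverable; both conventions
are first-class.

**Translational parameter T.** The mean number of individuals within a
radius `r_T` of each individual.  The default radius is `1.3·D`, strictly
between the first (D) and second (√3·D) shells of the triangular lattice,
so the crystal bulk gives a count of self + 6.  Both counting conventions
are exposed (`include_self`).  The *fragmented-phase plateau* is reported
with the exclusive count (focal individual not counted, column `T_excl` in
sweep outputs) for a substantive reason: at the standard density the
fragmented quasi-stationary states are frozen chain-like configurations in
which every agent's first metric neighbour sits at exactly D — not the
isolated pairs one might expect — and the measured plateau is 2.8 with the
self-inclusive count versus 1.8 with the exclusive count.  Only the
exclusive convention reproduces the known plateau value of about 2 for
this regime, so we take it to be the convention of the original analysis.
The radius choice barely matters (2.5 at `1.05·D`, self-inclusive): the
frozen states concentrate pair distances at exactly D.

**Domains of danger.** An individual's predation-risk proxy is the area
of its Voronoi polygon.  For a compact swarm inside a much larger box the
rim polygons are dominated by empty space, so the *occupied-region*
convention clips cells to the convex hull of the point set inflated by
D/2; the sum of occupied-region areas is then the inflated-hull area.  The
plain box-clipped areas are also available (`clip="box"`).  The area
*reduction* between two configurations is `1 − mean_area(final) /
mean_area(initial)`; under ideal packing (triangular lattice, spacing D)
the closed form is `1 − (√3/2) D² P / L²` ≈ 0.742 at the standard
parameters, matching the published "up to 75%".

**Clusters.** Connected components of the graph linking pairs closer than
`1.5·D` (a convention, stated in output metadata: between the bonded
distance D and the second shell √3·D ≈ 1.73·D).

## Experiments and problem sizes

All experiment protocols are pure functions of `(params, grids,
replicates, seed0)`: replicate seeds derive from `(seed0, grid value,
replicate index)` through `numpy.random.SeedSequence`, so grids can be
reordered or extended without perturbing existing cells, and identical
inputs give identical outputs bit for bit.

- **Attention sweep** (`sweep_alpha`): replicated runs to
  quasi-stationarity (or the sweep cap; such runs contribute their final
  state and are flagged — at P = 91 strict quiescence is rare on feasible
  horizons, while the order parameters and areas are stationary long
  before: the reduction changes by < 0.01 between 5·10⁴ and 2·10⁵
  sweeps).  Defaults: 24 angles over (0, 2π), 100 replicates per the
  original protocol, `--fast` drops to 10.  The cohesive regime used for
  the headline domain-of-danger number is α ∈ [60°, 165°] in 15° steps:
  below ~60° the dense disordered phase violates stress zones and
  over-compacts past the ideal-packing bound, above ~170° the swarm
  fragments.  These boundaries are empirical observations of this
  implementation; the published critical angles are not recoverable from
  the available text.
- **Speed sweep** (`sweep_speed`): mean convergence time per (v, P) at
  constant density (the box scales with √P), censored runs counted and
  reported but never averaged into `t_conv`; the optimal v per population
  and a power-law fit of `t_conv` against P at the optimum.  At P = 19
  the optimum sits near v ≈ 0.011 with censoring at v ≤ 0.005 and
  v ≥ 0.1.
- **Noise sweep** (`sweep_noise`): a fixed horizon of sweeps (default
  3000 in the CLI; the acceptance suite uses 20 000), Ψ6 and T on the
  final state, and the empirical transition point where mean Ψ6 crosses
  0.5 (measured around η ≈ 0.15–0.25 at α = 75°).  The published horizon
  is not recoverable; ours is stated in the output metadata.
- **Herd scenario** (`herd_scenario`): the crab-swarm parameterisation
  (P = 90, D = mean inter-individual distance = 0.1, v = mean attack
  speed = 0.0112, model units — the published unit exponents are
  redacted, so this is a qualitative reproduction), tracking
  A(t)/A(0), the occupied-region area normalised to its initial value,
  plus the mean-polygon reduction at the horizon and at quiescence.

## What the generator does and does not emulate

Initial conditions are i.i.d. uniform points at density P/L² ≈ 30 —
matching the field-scenario density after an alarm, not a structured herd.
The model omits everything a real swarm adds on top of relative
positioning: a common drift velocity, heterogeneous speeds, inertia,
perception error in distance (only direction noise is modelled), and
predator dynamics.  Passing tests therefore certify the geometry of the
interaction rule (phases, ordering, domain-of-danger reduction), not a
calibrated description of any particular species.

## Numerical choices

- Movement threshold 10⁻¹²: a target at |d − D| below it causes no move,
  preventing femtometre-scale jitter around the clamped distance.
- Absorbing/quiescence tolerance 10⁻⁹ on distances.
- Voronoi adjacency requires a shared edge longer than 10⁻¹²; interior
  agents are those whose cell clears the clip boundary by more than 10⁻⁹.
- Equidistant sector candidates tie-break to the lowest index; the sector
  boundary is closed.  Both are measure-zero choices fixed for
  reproducibility.
- The inner loops are numba-compiled; all randomness is drawn from a
  single numpy PCG64 generator per run, so a run is a pure function of
  its parameter set (including the seed).

## Known limitations

- Strict quasi-stationarity at P = 91 requires horizons far beyond the
  default sweep cap for most seeds (the original analysis also emphasises
  very long runs); finite-horizon final states are used where stated,
  with convergence flags preserved in every output.
- The exact published values of the phase-boundary angles, noise
  interval, T radius and quiescence window are reconstructions; each is a
  configurable parameter with its default and rationale stated above.
- Boundary handling (stopping at the wall) is untested against
  alternatives because agents never reach the wall in the studied
  regimes.
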