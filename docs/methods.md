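# Methods

## Model overview

`socdist` simulates ν mobile individuals in a rectangular region of
X × Y square feet over T discrete time epochs.  At every epoch the
proximity contact network G_t is rebuilt: an undirected tie joins two
individuals iff their Euclidean distance is at most the contact
threshold d, with the boundary case counting as a contact (the
threshold is closed).  Graph construction uses a k-d tree
(`scipy.spatial.cKDTree.query_pairs`, inclusive of the radius); the
test suite holds it equal to the naive O(n²) pairwise check.

Each epoch runs in a fixed order: (1) build the network at the current
positions; (2) propagate contagion potential on it; (3) score the
network; (4) run the configured relocation strategy; (5) apply the
flouting overlay; (6) clip and commit positions; (7) rebuild and
rescore; (8) apply the SEIRD transmission step on the *post-relocation*
network; (9) record counts, growth rate and R_t.  Contagion potential
is updated before relocation so the contagion-potential objective
scores the same network the optimizer sees; transmission acts after
relocation because the committed contacts are the ones people actually
hold during the epoch.  The driver is a plain epoch loop: the dynamics
are synchronous, so a discrete-event engine would add machinery without
adding behaviour.

## SEIRD dynamics

States are S, E, I, R, D; every individual is in exactly one.  A
susceptible with k infected contacts becomes exposed with probability
1 − (1−β)^k — a per-contact Bernoulli hazard, the standard
spatialization when the compartmental rates are enforced through a
contact network rather than through the differential equations
directly.  E → I with probability σ; an infected exits with probability
γ, to D with case-fatality fraction α and to R otherwise.  R and D are
absorbing; the population size is conserved (the dead remain in the
set).  Defaults (σ, γ, α, β) = (0.25, 0.1, 0.05, 0.55) follow common
COVID-19 parameterizations, giving R₀ = β/γ = 5.5 inside the nominal
3–6 band.

Two implementation details exist purely for reproducibility: all
transitions are computed on a state snapshot and applied simultaneously,
and each individual consumes exactly one uniform draw per step (for an
infected, u < γα ⇒ death, else u < γ ⇒ recovery — the joint
probabilities are unchanged).

Exposed individuals do not transmit by default.  Some COVID-era models
treat E as infective; the flag `SEIRDParams(exposed_infective=True)`
enables that variant without changing anything else.

The growth rate is G_t = (I_t − I_{t−1})/I_{t−1}, recorded as missing
when I_{t−1} = 0, and the effective reproduction number is
R_t = 1 + G_t/γ.  R_t series are noisy at these population sizes; a
Savitzky–Golay filter (`scipy.signal.savgol_filter`) smooths them, with
window 9 and polynomial order 2 as defaults — wide enough to suppress
single-epoch spikes over a 50–100 epoch horizon while following the
epidemic's rise and fall.

## Contagion potential

P_t(u) is 0 at t = 0, pinned to 1 while u is infected, and otherwise
Σ_{v∈n_t(u)} P_{t−1}(v) / M_t, where M_t is the maximum degree of the
epoch-t network ("per epoch" rather than a historical maximum: the
normalizer describes the current contact structure).  Since a node has
at most M_t neighbors each contributing at most 1, the value stays in
[0, 1].  An edgeless epoch (M_t = 0) gives every non-infected node 0:
no contacts, no acquired potential.  The overall potential Z_t(u) is
the running mean of P_1..P_t — over *elapsed* epochs when computed
mid-run, which coincides with the 1/T form at the horizon — pinned to 0
for R/D and 1 for I.  For homophily analysis, Z values are discretized
by rounding half-away-from-zero to one decimal (so 0.05 groups as 0.1;
banker's rounding would merge it with 0.0).

## Objectives

All three scores exclude recovered and dead individuals, who impose no
relocation pressure.  Susceptible and exposed are pooled because both
are asymptomatic and indistinguishable in the field.

* direct contact: the number of S/E–I ties.
* clustering: the number of triangles with ≥ 1 S/E member and ≥ 1 I
  member, each unordered triple counted once.  The predicate is the
  logical condition, not an enumerated list of state patterns.
* contagion potential: Σ |Z(u) − Z(v)| over ties among live (S/E/I)
  nodes.  With the indicator CP (1 on I, 0 elsewhere) this equals the
  direct-contact count — the objective is its continuous
  generalization.

Feasibility is a hard bound: a move is legal iff the displacement from
the epoch-start position is ≤ τ.  "Moves within τ on average" admits a
softer reading, but the optimizer's candidate set must be a hard ball
for the constraint to be checkable, so the bound is strict and the
uniform proposal lives in the closed τ-disk.

### Incremental scoring

Moving one node only changes the ties and triangles incident to it, so
the optimizer scores a candidate by a local delta: the node's
contribution at the proposed position minus its current contribution.
`ObjectiveEvaluator` keeps a dense boolean adjacency matrix (populations
here are at most a few thousand) and updates one row/column per
accepted move.  A property test holds every delta equal to the full
recomputation for all three objectives.

## Strategies

**Sampling.**  Within an epoch, sweeps visit all nodes in uniform-random
order, one at a time with all others fixed.  Each visit draws K
candidates (default 10; the count trades per-visit quality against
runtime, and staying put is always available since rejection keeps the
current position) uniformly in the τ-disk around the node's
*epoch-start* position — anchoring at the epoch start keeps the
per-epoch displacement bound intact no matter how many sweeps run.  The
best candidate is accepted only if it strictly lowers the global score;
ties keep the node in place, which makes the per-epoch score sequence
non-increasing and guarantees termination.  A Metropolis-style uphill
acceptance would also be defensible, but moves that fail to improve are
rejected outright, and monotone convergence is what makes the
convergence criterion meaningful.  The epoch ends when the fraction of
nodes relocated in the last sweep drops below the convergence index π
(default 0.4, the middle of the customary 0.3–0.5 band), or after
`max_sweeps` (default 20) as a safety cap.  Recovered and dead nodes
are skipped: their contribution to every objective is zero, so no
candidate can strictly improve.

**Grid.**  The region is tiled into √Z × √Z equal cores (Z a perfect
square).  Cores are half-open on their upper edges, with the region's
outer boundary closed, so every position belongs to exactly one core
and border ties break deterministically.  Each core is padded by τ on
every side (clipped to the region): since no node can out-travel τ in
one epoch, a member may stand anywhere in the padded bounds without
noticing the partition.  The map step optimizes each grid's members
independently — the grid's contact view is restricted to its own
members, which is what makes the grids embarrassingly parallel — with
candidates confined to the padded bounds; nodes may not leave them
during the map step.  The within-grid optimizer is the single-site
sampler (with its π criterion); this makes Z = 1 reproduce the global
sampling strategy *bit for bit* and makes the hybrid strategy (grids +
sampler) coincide with the grid strategy, which is why both entry
points share one implementation.  The exact joint optimization is
represented at desk scale by `exhaustive_optimize` (below).  The reduce
step reassigns every node whose final position lies in another grid's
core; membership after reduce is a permutation of the population.

Parallelism is a contract, not a mechanism: per-grid RNGs are derived
from integer seeds drawn once from the caller's generator, so any
execution order (or a process pool) gives identical results.  The
degenerate Z = 1 grid uses the caller's generator directly — one
independent unit needs no derivation.

**Distributed.**  Each node may move only after all its lower-id
contacts have moved, so node u's waiting time is the length of the
longest strictly-id-decreasing path ending at u (computed by one pass
in ascending id order).  Nodes then relocate exactly once, in
micro-round order, accepting the best strictly-improving candidate.
The acceptance delta involves only the moving node's neighborhood, so
the strategy needs no global knowledge; the global score appears in the
outcome purely as bookkeeping.  Mean waiting time grows with contact
density and shrinks with area, which the tests assert directionally.

**Flouting.**  With probability φ a node discards its recommendation
and performs a random τ-bounded move from its current position.
Flouting applies to destinations only, not to the distributed
schedule's ordering: ignoring a recommended location is a behavioural
choice, whereas the schedule is the coordination protocol itself.

**Random baseline.**  Every node takes one uniform τ-disk move per
epoch; strategy recommendations replace (never supplement) this motion.

## The exhaustive oracle

`exhaustive_optimize` enumerates the joint assignment space over a
lattice of candidate positions per node (a resolution × resolution grid
spanning the τ-disk, clipped to the region) and returns the minimizing
assignment.  It is limited to ≤ 6 nodes and ~2×10⁶ assignments; it
exists as the optimality yardstick for the scalable strategies, not as
a production path.  Because the lattice is a finite subset of the
continuous disk, the oracle is exact on instances where the true
optimum is attainable on the lattice (in particular wherever full
separation, score 0, is possible — the regime the proximity tests use).

## Synthetic populations

`generate_population` places n individuals independently and uniformly
in the region and seeds 70% susceptible / 30% infected by default
(susceptible count rounded half up), matching the standard study
conditions used throughout: d = 6 ft, τ = 25 ft, T = 50 epochs, and
population/area pairings such as 75 nodes in 100 × 50 ft.  Uniform
placement emulates a well-mixed open space — a plaza rather than a
street grid.  It does not reproduce uneven spatial density, erratic
individual itineraries, predetermined destinations, or map-constrained
movement; conclusions from passing tests are therefore about the
strategies' behaviour under spatially homogeneous mixing, not about any
particular city geometry.

## Experiment conventions

`run_experiment` replays the *identical* initial population (positions
and epidemic states) across iterations, with per-iteration RNGs derived
from `SeedSequence([seed, iteration])`, and reports unweighted epoch-wise
means — the fairness convention for comparing strategies.  Directional
comparisons in the tests use 10 iterations at ν = 75 (sampling vs
random cumulative counts) and 5 iterations per flouting level; these
sizes give comfortable separation between conditions (e.g. mean final
cumulative 22.1 vs 75.0) at interactive runtimes.

## Numerical choices and degenerate inputs

* Strict-improvement threshold 1e-12 on score deltas: the integer
  objectives change by ≥ 1, and CP deltas below this are float noise.
* Clipping to any axis-aligned box containing the anchor can only
  shrink each displacement component, so clipped candidates remain
  feasible.
* τ = 0 collapses every proposal to the current position; an edgeless
  network yields score 0 and a one-sweep epoch; an all-R/D population
  is inert under every strategy.
* Growth rate from I_{t−1} = 0 is recorded as missing (None/NaN) rather
  than inf; R_t inherits the gap.
* E-I index on an edgeless graph raises rather than returning 0: a
  proportion over zero ties is undefined, and silently coercing it
  would bias homophily averages.

## Known limitations

* The grid map step restricts each grid's contact view to its own
  members; ties crossing a border are invisible during the map step and
  only reappear after reduce.  This is inherent to the decomposition
  and is the price of parallelism the hybrid inherits.
* Single-site sampling is greedy (no uphill moves), so it can park in
  local minima; the oracle-proximity test quantifies how often that
  matters at desk scale.
* Wall-clock speed-up from actual multi-process execution is out of
  scope; the package guarantees scheduling-independent results instead.
* CP propagation uses the pre-relocation network each epoch, so a
  node's potential reflects the contacts it had when the epoch opened.
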