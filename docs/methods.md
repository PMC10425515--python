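# Methods

## Model

The fine-grained description is a population of point particles on an
unbounded 2-D plane (origin bottom-left, arbitrary length units, no
wrapping). Each particle carries named real-valued traits; trait kinds are
`linear`, `angular_degrees` (normalised to [0, 360) on construction) or
`positional`. Time is a non-negative integer step index; continuous time is
out of scope.

A coarse-graining is a partition of the alive particles into collectives.
Applying it replaces each block with one entity whose traits are
aggregates of the members' traits, whose position is the member centroid,
and whose dispersion is the maximal member distance from that centroid.

### Dynamics

Three deterministic one-step rules, applied identically to particles and
collectives:

* **ballistic** — move `speed` units along the current heading;
* **chemotaxis** — re-orient along the gradient of the summed resource
  field, then move;
* **phototaxis** — same on the light field; default sign −1 (flee).

Resource patches and light sources are isotropic exponential kernels,
`w · exp(−d/λ)` with per-source length scale λ. The exponential is a
stated modelling choice for a substance that "diffuses" from point
sources; only its monotone radial decay matters to the examples, since the
flight/approach direction under a single source is kernel-independent.
Gradients are analytic; at an exact extremum (zero gradient, including an
entity sitting on a source) the heading is left unchanged, which keeps the
dynamics deterministic without introducing an arbitrary angle. There are
no particle–particle interactions in the non-evolutionary dynamics — that
is what makes the per-entity-per-step operation costing exact — and no
spatial boundary.

### The prediction-error statistic

`delta_C` compares the truthful pathway (evolve particles, then
coarse-grain) with the projected pathway (coarse-grain, then evolve each
collective as one entity). Per-collective deltas are signed (truthful −
projected); the population summary used for the θ decision is the maximal
absolute per-collective error, with the Euclidean norm for positional
deltas. Positional comparisons additionally report the truthful members'
dispersion: the projection claims the entity is at a point, while in truth
it is distributed in space, and that discrepancy is part of what θ must
tolerate.

θ has no default. What error is tolerable depends on context and
measurement error, so it is a required parameter everywhere a verdict is
produced. The decision is strict: accept iff δ < θ; δ = θ rejects.

`best_partition` searches only the supplied candidate list and never
injects the singleton partition, which is trivially perfect (δ_C ≡ 0) and
uninteresting — compression is the point. Exact ties on the summary error
are re-evaluated at step counts {steps/2, steps, 2·steps} (integer,
clamped to ≥ 1), then broken by fewest blocks, then by lexicographic block
structure, so the search is fully deterministic.

`conditioned_delta` evaluates the per-trait errors separately in each
weighted environment state and reduces them to one scalar either as the
Euclidean norm across all elements or as their maximum; the max reduction
implements "below θ in every environment state" literally. The weights are
user-supplied occupancy probabilities; they validate the distribution and
select the support but do not rescale the reduction (k identical states
with error d reduce to d·√k and d respectively). No attempt is made to
estimate state probabilities from data. Per-trait errors are reduced on
their raw scales; optional per-trait thresholds (`Threshold.per_trait`)
are the provided way to handle traits of very different magnitude.

### Aggregation of directions

Angular traits aggregate by the plain arithmetic mean of degrees by
default, and the corresponding error is the plain (non-wrapped) absolute
difference. This pairing is deliberate: the aggregate of the incoherent
triplet 350/240/80 is ~223°, and its maximal deviation 143°, only under
plain-degree arithmetic; a circular mean and a wrapped error are provided
(`method="circular_mean"`, `wrap=True`) for users who prefer
rotation-invariant statistics, but they are never the default. The
aligned-fixture generator keeps each cluster's headings away from the
0/360 cut so the plain-degree convention is internally consistent.

### Birth–death extension and MLS1/MLS2

Generations are discrete, synchronous and non-overlapping: every particle
with at least `min_partners` partners within `interaction_radius`
produces `offspring_count` offspring at its own position (traits
inherited); all parents die. Asynchronous life cycles break the
particle→collective event mapping and are rejected with an error rather
than approximated.

Partner counting defaults to block-local (a particle's partners are
sought within its own collective), which is what makes the choice of
partition consequential for predicted reproduction; `partner_scope=
"global"` counts across the whole population. In
`coarse_graining_reproduction_delta` the truthful pathway always uses
global counting — it simulates the physical interaction structure, which
does not depend on how an observer has partitioned the population — while
the projected pathway sees only the collective-level summary (a
collective reproduces iff its member count exceeds `min_partners`). A
partition matching the interaction neighbourhoods therefore predicts
collective reproduction exactly, and a mismatched one sees apparently
stochastic reproduction it cannot explain.

Offspring collective formation: the offspring of one parent block, in
parent-id order, are chunked into ⌈n_offspring/block_size⌉ groups. The
convention is arbitrary but deterministic, and is replaceable via the
`offspring_grouper` callable; MLS2 accounting only requires that each
offspring collective trace to exactly one parent collective, which is
enforced and raises `MappingRuleError` otherwise.

MLS1 fitness aggregates offspring-particle counts per collective (mean or
sum); MLS2 counts offspring collectives. Under the mean mapping with
equal block sizes the mean MLS1 fitness equals the mean particle fitness
exactly — the commensurability expected at the start of a transition —
while MLS2 can order collectives differently from MLS1 (eight offspring
particles in two collectives vs. six in three), which is the decoupling
the two conventions are meant to expose.

### Operation budgets

The cost unit is one operation per entity per timestep (rules may declare
a higher `ops_per_step`). The horizon under budget B for n entities is
⌊B/(n·c)⌋; the simulation engine's ledger records the same unit, so
measured totals and closed-form costs agree exactly. Measurement costs
are acknowledged qualitatively only; no quantitative measurement-cost
model is asserted.

## Synthetic data

The clustered generators emulate a population of 12 cells in 4 spatial
clusters of 3. Cluster centres sit on a grid with separation 5× the
cluster spread (default spread 2 length units, so separation 10); members
scatter uniformly in a disc of radius spread/2, so a proximity radius of
2.5× spread cleanly isolates the clusters. The designated cluster carries
verbatim heading triplets — 240/220/200 (aligned) and 350/240/80
(scrambled) — while other clusters draw seeded headings: within ±20° of a
cluster mean in aligned mode (±20° being the designated cluster's own
maximal deviation), uniform on [0, 360) in scrambled mode. The two
variants share geometry bit-for-bit under a common seed, so they differ
only in heading coherence. The quartet generator places groups of four
particles at the corners of a square with diagonal < the interaction
radius (every member has exactly 3 partners) and separates quartets by
10× the radius; it returns the matched quartet partition and the
deliberately mismatched pair partition alongside.

What the generators do not emulate: measurement noise, heterogeneous
speeds, particle death outside the reproduction step, trait mutation or
heritable variation, and any real spatial scale — all lengths are
arbitrary units fixed by the fixture. Passing tests therefore show that
the statistic discriminates heading-coherent from heading-incoherent
collectives and interaction-matched from interaction-mismatched
partitions under clean, deterministic conditions; they do not show
robustness to noisy or partially observed data.

## Numerical choices

* Rounding is half-away-from-zero (`round_values`), so reported degrees
  are platform-independent.
* Population CSVs are written with `%.17g` floats and read with
  round-trip float parsing, making read∘write the exact identity.
* Gradient magnitudes below 1e-12 are treated as zero (heading kept).
* Partition candidates from `proximity_partitions` grow blocks greedily
  along proximity-graph edges from the lowest remaining id, taking the
  nearest frontier particle (ties to the lowest id); the bipartition
  enumerator is guarded at 20 ids (2²⁰−2 partitions).
* Problem sizes throughout the test-suite sweeps (12-particle clustered
  fixtures, ≤ 4 quartets, ≤ 9-particle enumeration searches, 20-seed
  paired sweeps) are desk-scale by design: every quantity of interest is
  exact or a strict ordering, and these sizes already exercise them.

## Known limitations

* Fine-graining (recovering particle states from collective states) is
  not provided: compression discards information by construction.
* Mutual-information-based individuality measures are out of scope; the
  statistic here is purely predictive error under compression.
* The bipartition enumerator handles only two-block (system/environment)
  partitions; general k-block candidates come from the proximity search.
* Collective ids are fixed within one analysis; membership change during
  a non-evolutionary prediction is an error rather than a tracked event
  (birth–death bookkeeping lives in the `mls` module).
* A temporal-stage reading of levels, in which a collective phase of a
  life cycle could carry *more* dimensions than the particle phase, is
  noted but not implemented.
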