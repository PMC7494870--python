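# Methods

## Lattice and symmetry

The icosahedral 60-mer core is represented as the dodecahedron graph: 20
vertices (E2 trimers) at the standard golden-ratio embedding — the points
(±1, ±1, ±1), (0, ±1/φ, ±φ), (±1/φ, ±φ, 0), (±φ, 0, ±1/φ) normalized to the
unit sphere — with vertex ids assigned by lexicographic sort of the rounded
coordinates, so canonical forms and class labels are stable across runs and
machines. Edges connect exactly the vertex pairs at the minimal Euclidean
separation (relative tolerance 1e-6), which yields the 30 bridge
interfaces; graph distances come from breadth-first search and are cached
as a full table. The octahedral 24-mer (cube graph, 8 vertices, 12 edges)
is built the same way, and user polyhedra can be supplied as JSON
(`{"coords": [[x,y,z],...], "edges": [[i,j],...]}`, 0-based ids); an edge
list that contradicts the constant nearest-neighbour criterion is rejected
rather than silently reinterpreted.

The symmetry group is built by exhaustive frame matching: a reference
vertex and one of its neighbours are mapped onto every (vertex, neighbour)
pair, the unique rotation carrying one orthonormal frame onto the other is
constructed, and it is kept if it is proper (det = +1) and permutes the
vertex set within 1e-9. Only proper rotations are admitted because the
core scaffold has a fixed handedness; the central inversion does map the
dodecahedral vertex set to itself but is deliberately excluded (and tested
as a negative control). This yields the icosahedral rotation group I
(order 60) and the octahedral group O (order 24) without hand-coded
generators, and degrades gracefully to the trivial group for asymmetric
user polyhedra.

Point groups are named from the element-order census of a stabilizer:
order-12 groups with 8 threefold and 3 twofold rotations are T; cyclic and
dihedral groups are recognized by the existence of a generator or of a
maximal cyclic subgroup plus the right number of twofolds. Closure and
presence of the identity are checked and violations raise an error.

## Occupancy, exclusion and classes

An occupancy is a set of occupied vertices; validity under an exclusion
rule means every occupied pair is at graph distance ≥ `min_distance`.
`min_distance = 3` encodes volume-occluding interior baskets (at least two
intermediate trimers between any two occupied ones), `min_distance = 2`
non-occluding trimers, `min_distance = 1` no exclusion. Enumeration is
depth-first extension adding only vertex ids above the current maximum, so
every valid subset appears exactly once; at these lattice sizes the full
enumeration is instantaneous (231 valid occupancies at distance ≥ 3, 5828
at ≥ 2).

Class identity is the canonical form: the lexicographically smallest sorted
image of the set over all 60 rotations. Each class records orbit size,
stabilizer order (their product is always the group order), point-group
label and a jammed flag (no single-vertex addition remains valid). The two
size-4 classes are rotation-inequivalent but exchanged by the central
inversion — genuine mirror counterparts. Aliases follow the field's usage:
X4S/Y4S for the saturated tetrahedral arrangements ("X" is the class with
the lexicographically smaller canonical tuple; the pairing with the two
deposited reconstructions is arbitrary without registering against the
maps, and nothing downstream depends on which is which), 3S/2S for jammed
sub-maximal states, 8S for the saturated non-occluding cube.

"Suboptimal" states are implemented as jammed-below-maximum (no further
addition possible) and "unsaturated" states as extendable subsets of a
maximal arrangement. We read the suboptimal 2S/3S configurations as
terminally blocked: that is the only reading under which a sequential
assembly process can stop short of saturation, and it is what makes the
15% prediction below well-defined.

## Sequential attachment and jamming

The naive assembly model is an irreversible Markov chain on occupancies:
start empty; at each step choose uniformly among the vertices whose
addition keeps the occupancy valid; absorb when none remains. Uniform
choice over *sites* is the minimal measure consistent with "attach
sequentially" — nothing in the geometry distinguishes allowed sites. The
exact absorbing-state distribution is computed by recursion with
memoization on canonical forms (the chain's law is symmetry-invariant, so
a state and its rotations share one memo entry), entirely in exact
rational arithmetic; only 11 canonical states exist at `min_distance = 3`.
The result: each tetrahedral class absorbs exactly 3/20 of the mass, the
jammed 3-baskets states 3/5, and the jammed antipodal pair 1/10. An
independent plain-state recursion (memoized on raw vertex sets, no
symmetry) reproduces the same rationals in the test suite, and seeded
Monte Carlo at 10^5 runs agrees within three binomial standard deviations.

Monte-Carlo simulation uses one numpy PCG64 generator per call, consumed
sequentially across runs, so identical (seed, n_runs) give bitwise
identical frequencies (reported as exact fractions count/n_runs).

The co-assembly variant grows the core itself in uniformly random vertex
order. A site becomes PX-competent at the moment it and its three
neighbours are all present — the weakest condition under which all three
of its bridge pockets exist, chosen because PX is known to bind partial
cores but the minimal fragment is not; each newly competent, non-excluded
site binds immediately with probability `p_bind`, ties in competence time
are broken uniformly, and after core completion the remaining allowed
sites fill as in the preformed-core chain. `p_bind = 0` reduces exactly to
the preformed-core law. There is no detachment in any mode: the model is
deliberately kinetic and irreversible, not thermodynamic. At `p_bind = 1`
the simulated saturation fraction rises to ≈ 0.36 (from the preformed-core
0.30) — binding during growth enriches the saturated tetrahedral outcomes,
the direction the co-assembly hypothesis requires, though the magnitude
depends on the unknown kinetics that `p_bind` only caricatures.

## Stoichiometry

The stoichiometry report derives every number from the lattice and the
enumeration at call time: `edge_monomer` mode caps bound PX at the edge
count (30 pockets → 2:1 E2:PX), `vertex_trimer` mode at three times the
maximum valid occupancy (24 monomers at distance ≥ 2; 12 at ≥ 3, i.e.
60:12 = 5:1). The two modes are mutually exclusive analyses — mixtures of
monomeric and trimeric PX on one core are not modelled. Of the previously
reported ratios, 2:1 and 5:1 have geometric counterparts here; 4:1
(15 monomers per core) does not, and the report flags it as unexplained
rather than forcing an interpretation.

## Synthetic populations and saturation estimation

The population module emulates the *statistical* structure of per-particle
interior classification, not the images: each particle has a true state
(tetrahedral-X, tetrahedral-Y with equal probability s/2 each, or
non-tetrahedral with probability 1 − s) and an observed label in {X, Y, N}
after a confusion step with two parameters — λ (lambda_loss), the
probability a truly tetrahedral particle is absorbed into class N
(sub-populations hidden by marginalized reconstruction), and η (eta_gain),
the probability a truly non-tetrahedral particle is misassigned to a
tetrahedral class, split evenly. Unsaturated and suboptimal interiors are
collapsed into "non-tetrahedral" because the classification cannot
separate them; consequently passing tests say nothing about how class N
decomposes in real data, and nothing here simulates orientation
assignment, defocus, or any image-level effect. No quantitative confusion
rates are known for real reconstructions; the defaults are λ = η = 0 and
the nonzero values used in tests (λ = 0.2, η = 0.05) are illustrative
operating points for parameter-recovery checks, not measurements.

Three observed counts carry two degrees of freedom, so (s, λ, η) is not
jointly identifiable; the estimator takes λ and η as fixed inputs and
maximizes the trinomial likelihood over s alone. The MLE is closed-form
(the score is linear in s), clipped to [0, 1] with a boundary flag; the
reported interval is the profile-likelihood set {s : 2ΔlogL ≤ χ²₀.₉₅(1)}
found by bisection, which behaves correctly at boundaries where the Wald
interval does not. When 1 − λ − η = 0 the data carry no information about
s and the fit is flagged non-identifiable with the full [0, 1] interval.
Coverage of the 95% interval, checked over 500 seeded replicates at
n = 10^4, is ≥ 93%.

## Problem sizes and numerical choices

All enumeration and exact-chain computations run in well under a second.
Default simulation sizes are chosen so every check completes comfortably
on one CPU: 10^5 runs for Monte-Carlo-versus-exact comparisons (binomial
3σ at that size resolves differences of ~0.3 percentage points), 500
replicates at n = 10^4 for interval coverage. Coordinate matching uses
1e-9 absolute tolerance (golden-ratio coordinates and frame-derived
rotation matrices are accurate to machine precision); the edge criterion
uses a 1e-6 relative band. All class probabilities in the exact chain are
`fractions.Fraction` — no floating-point tolerance is involved until a
number is printed.

## Known limitations

- Sites are all-or-none: partial pocket engagement (a trimer using fewer
  than its three bridges) and mixed monomer/trimer populations are out of
  scope, as are binding energetics and detachment.
- The exclusion rule is a hard graph-distance threshold; real volume
  occlusion is continuous and conformation-dependent.
- The X/Y alias assignment is a labelling convention, not a claim about
  which deposited map is which.
- The co-assembly model's competence rule and `p_bind` compress unknown
  nucleation/growth kinetics into one parameter; its outputs are
  directional, not quantitative predictions.
- The confusion model is label-level only; it cannot validate, and is not
  validated by, any particular image-processing pipeline.
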