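# Methods

`protknot` characterizes the entanglement of protein backbones at four
levels: probabilistic knots of the open chain, planar knotoids, deterministic
knots in covalent loops, and cystine-knot motifs. This note records the
models, the numerical choices, and what the synthetic fixtures do and do not
emulate.

## Backbone model

A chain is reduced to its Cα trace, an open polygonal curve in ångströms.
Missing residues (gaps in the author numbering) contribute no vertices: the
connecting segment is implicitly straight. Multi-model files use the first
model; alternate locations resolve to the highest-occupancy conformer, ties
broken by altloc letter. These choices match single-conformer analysis and
keep the curve well defined for any deposited structure.

## KMT reduction

Before any invariant is computed the curve is simplified by triangle
elision: vertex `v_i` is removed when no other segment of the curve meets
the triangle `(v_{i-1}, v_i, v_{i+1})`. Each elision is an ambient isotopy,
so the knot type of a closed curve is preserved exactly. Intersection
predicates are conservative — coplanar or boundary-grazing configurations
block the elision rather than risk a strand passage — and the sweep runs to
a fixed point, making the reduction idempotent.

Open chains analyzed as knotoids need one extra constraint that is easy to
miss: an elision triangle whose *projection* sweeps across an endpoint
performs a forbidden endpoint move even though the 3D curve is merely
isotoped. Passing the projection direction to `kmt_reduce` additionally
forbids triangles that intersect the two lines through the endpoints
parallel to that direction. With this "pillar" rule the Turaev loop bracket
was unchanged on 300/300 random open chains; without it, nontrivial
knotoids can collapse to the trivial one.

## Projection and diagrams

A generic projection direction maps the curve to a planar diagram: all
transverse segment-pair crossings, each with over/under resolved by depth
and a sign from the right-hand rule. Genericity is enforced (no crossing
within 1e-7 of a segment end, no coincident depths, no triple points); a
degenerate direction is rotated by 1e-6 rad about a fixed axis sequence and
retried up to 10 times, keeping runs reproducible. The diagram retains both
the extended Gauss code and the planar geometry of the projected polyline —
the latter is needed by the knotoid bracket, which must decide whether a
state loop encloses the open arc.

## Knot invariants

The Alexander polynomial Δ(t) comes from the Wirtinger/Fox-calculus
incidence matrix: one row per crossing (entries 1−t, t, −1 at the over,
under-in and under-out arcs for a positive crossing; the mirrored pattern
for a negative one), delete one row and one column, take the determinant.
Determinants are computed exactly: fraction-free (Bareiss) integer
evaluation at n+1 points followed by exact Lagrange interpolation, then
normalization to lowest degree 0 and Δ(1) = +1. |Δ(−1)| is the knot
determinant.

HOMFLY-PT P(a, z) uses the skein relation `a·P(L+) − a⁻¹·P(L−) = z·P(L0)`
with unknot ↦ 1. The recursion always resolves the first crossing (in
traversal order) whose first visit passes under: switching it moves the
diagram toward a descending — hence trivial — one, smoothing it removes a
crossing, so termination is guaranteed. Codes are simplified by
combinatorial Reidemeister I/II moves at every step and memoized; the
default crossing cap is 30, beyond which callers fall back to
Alexander-only naming.

Knot types are named against a packaged table of prime knots through 7
crossings keyed by the normalized Alexander coefficient vector, which
separates all 15 entries (self-checked on load). Chirality is resolved by
HOMFLY-PT only: if P differs from its a→a⁻¹ image, the suffix is `+` when
the coefficient mass sits at positive powers of `a` — the convention makes
the packaged torus-knot parametrization `3_1+`. An Alexander polynomial
that factors as a product of two table entries is reported `composite`;
anything else unmatched is `unknown`.

## Knotoids and the loop bracket

A knotoid is the diagram of an open curve up to Reidemeister moves that
avoid the endpoints; because the ambient surface is the plane, a state
loop encircling the open arc cannot be removed, and tracking such loops
refines the classification beyond the spherical one. The invariant is a
writhe-normalized bracket state sum in Z[A^±1, u^±1]: each crossing is
smoothed both ways (for a positive crossing the A-smoothing is the
oriented one), a state contributes A^(#A−#B), ordinary loops contribute
δ = −A² − A⁻², loops enclosing the arc contribute the loop variable `u`,
and the total is multiplied by (−A³)^(−w). Normalized this way,
bracket(trivial arc) = 1, and invariance under endpoint-avoiding R1/R2/R3
moves is property-tested with explicit move constructions. Enclosure is
decided geometrically by the winding number of the traced state loop
around the arc's endpoint, which is why diagrams carry planar geometry.

Classification matches the bracket against reference diagrams shipped as
small 3D polylines (k0.1, k2.1, k3.1, k3.2 and mirrors), whose brackets
are computed on load and self-checked for pairwise separation. Two
conventions are fixed by the package: `k3.1` is the knotoid of the open
right-handed trefoil (the same parametrization that names `3_1+`), and
`k3.2` is the 3-crossing class distinct from both `k2.1±` and `k3.1±`
(found by exhaustive search over random diagrams; it is u-free and
irreducible). Planar-only classes outside the table — e.g. the 1-crossing
knotoid whose bracket carries `u` and whose spherical shadow (u→δ) is
trivial — report `unknown`. The state sum is exponential in the crossing
number and is capped at 16 crossings; larger diagrams also report
`unknown` rather than stalling.

## Probabilistic knots and knotoids

An open chain is closed through single points sampled on a sphere of
radius 100× the chain extent centred on the centroid — at that radius the
choice of closure scheme is immaterial. The knot spectrum is the
distribution of knot types over the closure points; the knotoid
distribution is the distribution of knotoid types over projection
directions. Direction sets default to a deterministic Fibonacci lattice
(reproducible bit for bit); a seed switches to uniform random directions
for convergence studies. The representative of either distribution is the
dominant (highest-probability) type, with ties broken toward the trivial
type and then lexicographically; a chain is called knotted only when the
dominant type is non-trivial. 100 closure points and 100 directions are
the defaults; on the deep trefoil fixture the dominant probability moves
by less than 0.1 between 100 and 400 samples.

## Fingerprints, cores, slipknots

The fingerprint matrix assigns each subchain (start, end) its dominant
type. Cells are evaluated on a stride grid (default stride n/100, keeping
the cost near 5000 subchain analyses) with reduced per-cell sampling
(default 20) and the whole-chain corner recomputed at full sampling;
subchains shorter than 5 residues are skipped as unable to entangle. The
knot core — the shortest subchain with the whole chain's type — is found
on the grid and then refined to single-residue precision: bisection along
each boundary first, then a bounded minimal-length sweep within one
stride of the grid cell. The sweep exists because dominance is not
exactly monotone near the 50% boundary, so pure bisection can stall in a
local minimum several residues from the true optimum; with the sweep the
refined core matches an exhaustive per-residue scan to ±2 residues on the
60-residue test fixture at equal sampling. Labels follow the standard
definitions: knot (whole chain non-trivial), slipknot (whole chain
trivial, some subchain non-trivial), and the knotoid analogues.

## Covalent loops and deterministic knots

Disulfide bridges are the union of declared records (SSBOND/struct_conn)
and geometric SG–SG pairs within 2.5 Å (greedy closest-pair, one bridge
per SG); ion bridges connect every pair of non-adjacent residues whose
side-chain O/N/S atoms lie within 3.0 Å of the same metal ion. The bond
types are standard but no thresholds are canonical, so both cutoffs are
configurable and echoed in the output metadata. Amide bonds and side-chain concatenations are accepted
only as user-declared bridges.

The backbone plus its bridges forms a graph (nodes: bridged residues;
edges: backbone intervals and bridges). All simple cycles using up to
`max_bridges` bridges (default 2, covering every published motif shape
while bounding combinatorics) are enumerated by DFS and cross-checked
against exhaustive search in tests; the free termini are never used as
connectors. Each loop's geometry is the Cα sub-polylines joined by
straight Cα–Cα bridge segments (SG-level geometry would change lengths
but rarely topology), and its knot type is computed deterministically —
no closure ambiguity exists for a genuinely closed loop. Loops are
rendered in the `4-c-11-b-23-c-21` notation (chain segments `-c-`,
bridges `-b-`, closing bridge implicit) with a full parser for the
reverse direction. N→C paths through the same graph ("bridged open
paths") feed the probabilistic pipeline for chains whose bridges shortcut
the backbone.

## Cystine knots

A cysteine knot is three disulfides of which two close a covalent loop
pierced by the third. "Pierced" is made geometric: the loop polygon is
spanned by a centroid-fan triangulation and the signed transversal
crossings of the candidate bridge segment are counted; |count| = 1 is a
piercing (an odd count ≥ 3 is reported with a `multiple_piercing` flag).
Degenerate incidences jitter the fan apex deterministically and retry;
the count is topological once crossings are transversal, verified by
apex-perturbation tests and a brute-force per-triangle oracle. Every
unordered triple of disulfides is tested with all three piercer choices
and no sequence-distance filter, so motifs of any span are reported.
Classes: `cyclic` when the chain is head-to-tail cyclized (terminal
Cα–Cα ≤ 5 Å or a declared amide bond); otherwise by which bridge pierces
the canonical arrangement — the 1–4/2–5 loop threaded by 3–6 is
`growth_factor`, the 2–5/3–6 loop threaded by 1–4 is `inhibitor`; other
permutations return `other` with the bridges available for inspection.
`verify_ck_loops_unknotted` confirms the defining property that every
covalent cycle in the motif is unknotted, and flags structures that also
carry a deterministic knot.

## Synthetic fixtures

The generators produce protein-scale geometry deterministically from a
seed. The (2,3) torus polygon is the trefoil reference; the open trefoil
removes one edge and retracts the ends radially so closure is nearly
unambiguous; the slipknot continues the open trefoil with a tail that
retraces the knotted stretch at a small outward offset, cancelling the
whole-chain entanglement while leaving the knotted subchain intact; the
bridged-loop fixture adds a disulfide across that stretch, giving an
unknotted backbone with a trefoil covalent loop; the cystine-knot
fixtures place a planar ring of two arcs plus two bridges with the third
bridge running through its centre, in all three class arrangements, with
an `expand` factor that stretches the sequence span without changing the
geometry. Fixtures emulate the topology and scale of real chains, not
their chemistry: no side chains beyond SG, no thermal disorder unless
noise is requested, and boundary sharpness (how quickly a subchain loses
its knot type) that is cleaner than in real proteins — passing tests
demonstrate correctness of the topological machinery, not detection
power on noisy experimental structures.

## Problem sizes and costs

Default analyses use 100 closures/directions for whole chains and 20 per
fingerprint cell. The test suite uses 40–120-vertex fixtures, 10–20
samples per fingerprint cell, and caps bracket state sums at 16 crossings
and HOMFLY at 30; these sizes keep every pipeline stage exercised at full
fidelity while the complete suite runs in a few minutes.
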