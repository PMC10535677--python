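# Methods

## The descriptors

All ten indices are edge sums of weights built from the 2-distance degrees of
the edge's endpoints. deg₂(v) counts vertices at shortest-path distance
exactly 2 from v — not walks: a vertex adjacent to v is never in its
2-neighbourhood even if a 2-walk reaches it. Distances are unweighted hop
counts on the simple graph; bond order is ignored throughout, matching the
usual molecular-graph abstraction for these descriptors.

deg₂ is computed by a depth-limited BFS from every vertex (cutoff 2), which
is O(V·E) overall and takes well under a second even on the largest graphs
this package targets (a few thousand vertices). An independent oracle
computes deg₂ from the boolean square of the adjacency matrix
(u counts iff (A²)ᵤᵥ > 0, Aᵤᵥ = 0, u ≠ v); it exists only to cross-check the
BFS route in tests and in the acceptance script, never to replace it.

Disconnected graphs are accepted everywhere: unreachable pairs simply
contribute nothing to deg₂, and BFS marks unreachable vertices by absence
rather than a finite sentinel. This keeps every operation total; the ribbon
families themselves are connected.

## Numerical policy

The eight polynomial indices (lm1 … hlgo2) are evaluated in Python's
arbitrary-precision integer arithmetic — values reach ~4·10⁸ on the tabulated
range and must be bit-exact, and the approach costs nothing at this scale.
The two connectivity indices (slgo, plgo) involve irrational per-class
weights 1/√w; the default is double precision, with `exact=True` returning a
sympy expression (sums of integer multiples of 1/√w). Float and symbolic
evaluation agree to ≤ 1e−12 relative error on all generated ribbons the
tests cover. A partition class with a non-positive radicand (any endpoint
pair where (a+b)+ab or (a+b)·ab is 0, e.g. both endpoints with deg₂ = 0)
raises an error naming the class: silently skipping classes would change the
mathematical object being summed.

Edge-partition keys are unordered (sorted) pairs, since the class
E_{a,b} is symmetric in its endpoint values.

## The ribbon families

Both generators realize the contracted-bridge abstraction of γ-graphyne:
benzene hexagons are 6-cycles of ring carbons, hexagon centres sit on a
triangular lattice, and each acetylenic −C≡C− linkage between two hexagons is
collapsed to a single edge joining one carbon of each ring. Each of a ring's
six carbons "owns" one of the six lattice directions and bridges outward
exactly when a neighbouring ring is present (and not pruned) in that
direction. Under this model a ring carbon has deg₂ = 2 + (bridges on its two
ring neighbours) + 2·(its own bridge), which is what confines the partition
classes to deg₂ ∈ {2, 3, 5, 6} for these families.

**GNR(m, n)** is the hexagonal triangular-lattice patch with side lengths
(2, 2m, 2n) rings — constructed as the (2m+1)×(2n+1) axial rhombus minus the
two corner rings that touch no interior ring. Interior rings, a
(2m−1)×(2n−1) block, keep all six bridges. On each straight side, the rings
that would otherwise carry four bridges drop alternate side-parallel bridges;
those rings form a path on each side, so the perfect matching of dropped
bridges is unique and the construction is fully deterministic. Every boundary
ring ends up with exactly three bridges in contiguous directions, which is
precisely the condition that excludes deg₂ = 4 vertices and yields the
five-class partition. The patch-shape and pruning rule were derived from the
partition cardinality polynomials themselves (ring census: (2m−1)(2n−1)
fully-bridged rings, 4m+4n−2 three-bridge boundary rings, 12mn bridges); the
build then re-verifies counts and partition on every call and raises
`RibbonValidationError` on any mismatch, so the cardinality formulas — not
the construction — remain the binding ground truth.

**ZGNR(n)** is a zigzag strip of n+2 rings alternating between two lattice
rows, with every lattice adjacency bridged: consecutive rings and
next-nearest rings, 2n+1 bridges in all. The two end rings carry two
bridges, their neighbours three, and the n−2 middle rings four — reproducing
the seven-class partition printed for n > 2 (at n ≤ 2 there are no
four-bridge rings, which is why the partition formulas and the builder
require n > 2).

Ring row, ring column and hexagon site (0–5) are recorded as vertex labels
so constructions are auditable; they carry no semantic weight. Planar
coordinates (MOL/XYZ export) are a visualization aid only — all atoms
carbon, all bonds single, no claim about real graphyne geometry.

## Closed forms and reconciliation

The closed-form catalog stores the published polynomial formulas for the
eight integer indices of each family coefficient-for-coefficient **as
printed**. Independent re-derivation from the partition cardinalities shows
three of the zigzag formulas carry arithmetic slips:

| index | printed      | implied by the partition |
|-------|--------------|--------------------------|
| hlm1  | 794n + 640   | 794n + 384               |
| lgo1  | 272n + 162   | 274n + 162               |
| lgo2  | 2064n + 348  | 2068n + 348              |

The catalog is not "corrected": `reconcile()` computes both routes and
reports per-index match flags, and the mismatches above are exactly the
flags it raises for the zigzag family. For the rectangular family, graph
route and closed forms agree on all eight indices everywhere the tests
probe. The published simplified radical expressions for SLGO/PLGO are
typographically ambiguous and are deliberately not catalogued; the two
connectivity indices are always evaluated from their defining sums.

`reproduce_table` emits the tabulated grids (rectangular diagonal
(1,1)…(8,8); zigzag n = 3…9) from the closed forms, optionally alongside
graph-route columns. Output is pure integer arithmetic and bit-identical
across runs.

## Test fixtures and scope

Test graphs are tiny deterministic structures (paths, cycles, stars,
cliques, seeded Erdős–Rényi draws) plus the generated ribbons; the random
fixtures exercise irregular deg₂ patterns the ribbons cannot, including
deg₂ = 0 endpoints and disconnected graphs. What passing tests establish is
exact agreement between four independent routes — per-edge brute force,
partition-weighted sums, the adjacency-matrix oracle and the closed forms —
on these families; they say nothing about descriptor quality on real
molecule datasets, which is out of scope, as are weighted/directed graphs,
3-D geometry, other graphyne polymorphs and periodic boundary conditions.

Problem sizes used in tests and the acceptance script: ribbons up to
GNR(8, 8) (1722 vertices, 2586 edges) and ZGNR(9), structure validation over
m, n ∈ {1..4} and n ∈ {3..9}, and 200 seeded 30-vertex random graphs for the
oracle equivalence check — the full range the reference tables cover, at
desk scale.
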