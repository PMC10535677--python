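# leapdeg

Leap (2-distance-degree) topological indices of molecular graphs, with
generators for γ-graphyne nanoribbon structures.

Topological indices are graph invariants used as molecular descriptors in
QSPR/QSAR modelling. While the classical Zagreb-type indices are built from
ordinary vertex degrees, the *leap* indices replace the degree with the
**2-distance degree** deg₂(v) — the number of vertices at shortest-path
distance exactly 2 from v. For a molecular graph Γ with edge set E(Γ), and
writing a = deg₂(u), b = deg₂(v) for an edge uv, the package computes

| id    | index                                | per-edge weight          |
|-------|--------------------------------------|--------------------------|
| lm1   | first leap Zagreb LM₁                | a + b                    |
| lm2   | second leap Zagreb LM₂               | a·b                      |
| hlm1  | first hyper leap Zagreb HLM₁         | (a + b)²                 |
| hlm2  | second hyper leap Zagreb HLM₂        | (a·b)²                   |
| lgo1  | first leap gourava LGO₁              | (a + b) + a·b            |
| lgo2  | second leap gourava LGO₂             | (a + b)·(a·b)            |
| hlgo1 | first hyper leap gourava HLGO₁       | ((a + b) + a·b)²         |
| hlgo2 | second hyper leap gourava HLGO₂      | ((a + b)·(a·b))²         |
| slgo  | sum-connectivity leap gourava SLGO   | 1/√((a + b) + a·b)       |
| plgo  | product-connectivity leap gourava    | 1/√((a + b)·(a·b))       |

each summed over all edges. The eight polynomial indices are computed in
exact integer arithmetic; the two connectivity indices default to floating
point with an opt-in exact symbolic mode.

The index evaluation uses the **edge partition technique**: edges are grouped
by the unordered pair (deg₂(u), deg₂(v)), so an index collapses to a weighted
sum over a handful of partition classes.

The package also generates two carbon-nanoribbon graph families whose
partitions admit closed forms — the rectangular γ-graphyne nanoribbon
GNR(m, n) and the zigzag γ-graphyne nanoribbon ZGNR(n) — using the
contracted-bridge abstraction (each acetylenic −C≡C− linkage between benzene
hexagons is collapsed to a single edge between ring carbons). Every build
self-validates its vertex count, edge count and deg₂ edge partition against
the family's reference cardinality polynomials, e.g. for GNR(m, n):

    |V| = 24mn + 12m + 12n − 6,   |E| = 36mn + 12m + 12n − 6
    |E₂,₃| = 8m+8n−4,  |E₃,₅| = 8m+8n−4,  |E₅,₅| = 2m+2n+2,
    |E₅,₆| = 12m+12n−12,  |E₆,₆| = 36mn−18m−18n+12

## Worked example

All ten indices of the smallest rectangular ribbon GNR(1, 1) (42 atoms,
54 bonds):

```sh
$ leapdeg compute --family gamma --m 1 --n 1
{
  "structure": "gamma_nanoribbon",
  "m": 1,
  "n": 1,
  "lm1": 492,
  "lm2": 1194,
  "hlm1": 4848,
  "hlm2": 33234,
  "lgo1": 1686,
  "lgo2": 12444,
  "hlgo1": 62970,
  "hlgo2": 4104888,
  "slgo": 10.740630159524432,
  "plgo": 4.903737192516645
}
```

LM₁ = 492 is the sum of deg₂(u) + deg₂(v) over the 54 bonds; equivalently,
from the partition, 5·12 + 8·12 + 10·6 + 11·12 + 12·12 = 492. The hyper
variants square each per-edge term, which is why HLGO₂ is already ~4·10⁶ on
this small patch; SLGO/PLGO are the corresponding reciprocal-square-root sums.

Generating a structure prints its self-validation summary:

```sh
$ leapdeg generate --family zigzag --n 3 --out zz3.txt
zigzag_nanoribbon {'n': 3}: |V|=30 |E|=37
deg2 partition: {(2, 2): 2, (2, 3): 8, (3, 3): 1, (3, 5): 10, (5, 5): 7, (5, 6): 6, (6, 6): 3}
partition check: PASS
```

and `leapdeg compute --edge-list zz3.txt` reproduces the same index values
from the written file. Arbitrary molecular graphs can be supplied the same
way (one whitespace-separated edge per line, `#` comments).

The closed-form tables for both families, and the reconciliation of the
graph route against the closed forms, are available as:

```sh
leapdeg reproduce --table 3 --format markdown
leapdeg reconcile --family zigzag --n 5
```

Python API: `build_gamma_nanoribbon`, `build_zigzag_nanoribbon`,
`compute_indices`, `edge_partition`, `k_distance_degrees`,
`evaluate_closed_form`, `reconcile`, `reproduce_table` — see docstrings and
`docs/methods.md`.

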