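"""Generators for gamma-graphyne nanoribbon molecular graphs.

Both families use the *contracted-bridge* abstraction of gamma-graphyne: each
benzene hexagon is six ring carbons, and each acetylenic -C#C- linkage between
two hexagons is collapsed to a single edge joining one carbon of each ring.
Hexagon centres then live on a triangular lattice and each of a ring's six
carbons "owns" one of the six lattice directions, bridging outward when a
neighbouring ring is present in that direction.

``GNR(m, n)`` (rectangular gamma-graphyne nanoribbon) is the hexagonal
triangular-lattice patch with side lengths ``(2, 2m, 2n)`` rings —
equivalently the ``(2m+1) x (2n+1)`` axial rhombus minus the two corner rings
that touch no interior ring.  Interior rings keep all six bridges; on each
straight side the rings that would otherwise carry four bridges drop
alternate side-parallel bridges (the unique perfect matching on each side),
leaving every boundary ring with exactly three bridges in contiguous
directions.  ``ZGNR(n)`` (zigzag ribbon) is a strip of ``n + 2`` rings in
which consecutive and next-nearest rings are bridged (``2n + 1`` bridges).

Every build self-validates its vertex count, edge count and 2-distance-degree
edge partition against the family's reference cardinality polynomials and
raises if any of them fail.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import MolecularGraph, edge_partition

__all__ = [
    "RibbonSpec",
    "RibbonValidationError",
    "build_gamma_nanoribbon",
    "build_zigzag_nanoribbon",
    "build_ribbon",
    "gamma_expected_counts",
    "gamma_expected_partition",
    "zigzag_expected_counts",
    "zigzag_expected_partition",
    "planar_layout",
    "to_xyz",
    "to_mol_block",
]

# axial-coordinate lattice directions in cyclic (counter-clockwise) order:
# E, NE, NW, W, SW, SE.  Ring site s bridges in direction _DIRS[s].
_DIRS = ((0, 1), (1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1))
_DIR_INDEX = {d: s for s, d in enumerate(_DIRS)}


class RibbonValidationError(AssertionError):
    """A generated ribbon failed its own count/partition postconditions."""


@dataclass(frozen=True)
class RibbonSpec:
    """Family identifier plus size parameters for a generated structure."""

    family: str  # "gamma_nanoribbon" | "zigzag_nanoribbon"
    n: int
    m: int | None = None

    def __post_init__(self) -> None:
        if self.family == "gamma_nanoribbon":
            if self.m is None or self.m < 1 or self.n < 1:
                raise ValueError("gamma_nanoribbon requires m >= 1 and n >= 1")
        elif self.family == "zigzag_nanoribbon":
            if self.m is not None:
                raise ValueError("zigzag_nanoribbon takes a single parameter n")
            if self.n <= 2:
                raise ValueError("zigzag_nanoribbon requires n > 2")
        else:
            raise ValueError(f"unknown family {self.family!r}")


def gamma_expected_counts(m: int, n: int) -> tuple[int, int]:
    """Reference vertex and edge counts of GNR(m, n)."""
    return 24 * m * n + 12 * m + 12 * n - 6, 36 * m * n + 12 * m + 12 * n - 6


def gamma_expected_partition(m: int, n: int) -> dict[tuple[int, int], int]:
    """Reference five-class deg2 edge partition of GNR(m, n)."""
    return {
        (2, 3): 8 * m + 8 * n - 4,
        (3, 5): 8 * m + 8 * n - 4,
        (5, 5): 2 * m + 2 * n + 2,
        (5, 6): 12 * m + 12 * n - 12,
        (6, 6): 36 * m * n - 18 * m - 18 * n + 12,
    }


def zigzag_expected_counts(n: int) -> tuple[int, int]:
    """Reference vertex and edge counts of ZGNR(n)."""
    return 6 * n + 12, 8 * n + 13


def zigzag_expected_partition(n: int) -> dict[tuple[int, int], int]:
    """Reference seven-class deg2 edge partition of ZGNR(n), valid for n > 2."""
    return {
        (2, 2): 2,
        (2, 3): 8,
        (3, 3): n - 2,
        (3, 5): 2 * n + 4,
        (5, 5): n + 4,
        (5, 6): 2 * n,
        (6, 6): 2 * n - 3,
    }


def _assemble(rings: list[tuple[int, int]], bridges: set[frozenset]) -> MolecularGraph:
    """Expand rings (6 carbons each, site s in direction _DIRS[s]) and bridges
    into the contracted-bridge molecular graph."""
    vertex_id: dict[tuple[tuple[int, int], int], int] = {}
    labels: dict[int, tuple[int, int, int]] = {}
    for ring in sorted(rings):
        for site in range(6):
            vid = len(vertex_id)
            vertex_id[(ring, site)] = vid
            labels[vid] = (ring[0], ring[1], site)  # (ring row, ring column, site)
    edges = []
    for ring in rings:
        for site in range(6):
            edges.append((vertex_id[(ring, site)], vertex_id[(ring, (site + 1) % 6)]))
    for bridge in bridges:
        a, b = sorted(bridge)
        d = (b[0] - a[0], b[1] - a[1])
        edges.append(
            (vertex_id[(a, _DIR_INDEX[d])], vertex_id[(b, _DIR_INDEX[(-d[0], -d[1])])])
        )
    return MolecularGraph.from_edges(len(vertex_id), edges, labels=labels)


def _validate(
    graph: MolecularGraph,
    expected_v: int,
    expected_e: int,
    expected_classes: dict[tuple[int, int], int],
    what: str,
) -> MolecularGraph:
    if graph.n_vertices != expected_v:
        raise RibbonValidationError(
            f"{what}: built {graph.n_vertices} vertices, expected {expected_v}"
        )
    if graph.n_edges != expected_e:
        raise RibbonValidationError(
            f"{what}: built {graph.n_edges} edges, expected {expected_e}"
        )
    got = dict(edge_partition(graph, 2).classes)
    if got != expected_classes:
        raise RibbonValidationError(
            f"{what}: deg2 edge partition mismatch: built {sorted(got.items())}, "
            f"expected {sorted(expected_classes.items())}"
        )
    return graph


def _lattice_bridges(rings: set[tuple[int, int]]) -> set[frozenset]:
    out: set[frozenset] = set()
    for r in rings:
        for d in _DIRS:
            q = (r[0] + d[0], r[1] + d[1])
            if q in rings:
                out.add(frozenset({r, q}))
    return out


def build_gamma_nanoribbon(m: int, n: int) -> MolecularGraph:
    """Contracted-bridge GNR(m, n) molecular graph, self-validated.

    Vertex labels are ``(ring row, ring column, site)`` with rings on axial
    triangular-lattice coordinates.
    """
    if m < 1 or n < 1:
        raise ValueError("gamma nanoribbon requires m >= 1 and n >= 1")
    rings = {(i, j) for i in range(2 * m + 1) for j in range(2 * n + 1)}
    rings -= {(0, 0), (2 * m, 2 * n)}  # corners with no interior neighbour
    bridges = _lattice_bridges(rings)
    # On each side, rings with four lattice neighbours shed one side-parallel
    # bridge; the degree-4 rings form a path whose perfect matching is unique.
    removed: set[frozenset] = set()
    for j in range(2, 2 * n - 1, 2):  # bottom row (i = 0)
        removed.add(frozenset({(0, j), (0, j + 1)}))
    for j in range(1, 2 * n - 2, 2):  # top row (i = 2m)
        removed.add(frozenset({(2 * m, j), (2 * m, j + 1)}))
    for i in range(2, 2 * m - 1, 2):  # left column (j = 0)
        removed.add(frozenset({(i, 0), (i + 1, 0)}))
    for i in range(1, 2 * m - 2, 2):  # right column (j = 2n)
        removed.add(frozenset({(i, 2 * n), (i + 1, 2 * n)}))
    graph = _assemble(sorted(rings), bridges - removed)
    ev, ee = gamma_expected_counts(m, n)
    return _validate(graph, ev, ee, gamma_expected_partition(m, n), f"GNR({m},{n})")


def build_zigzag_nanoribbon(n: int) -> MolecularGraph:
    """Contracted-bridge zigzag ribbon ZGNR(n) molecular graph, self-validated.

    A strip of ``n + 2`` rings alternating between two lattice rows; all
    lattice adjacencies (consecutive and next-nearest rings) are bridged.
    """
    if n <= 2:
        raise ValueError("zigzag nanoribbon requires n > 2")
    rings = {(t % 2, t // 2) for t in range(n + 2)}
    graph = _assemble(sorted(rings), _lattice_bridges(rings))
    ev, ee = zigzag_expected_counts(n)
    return _validate(graph, ev, ee, zigzag_expected_partition(n), f"ZGNR({n})")


def build_ribbon(spec: RibbonSpec) -> MolecularGraph:
    if spec.family == "gamma_nanoribbon":
        return build_gamma_nanoribbon(spec.m, spec.n)
    return build_zigzag_nanoribbon(spec.n)


# --- cosmetic planar export (visualization aid only, no correctness weight) ---

_RING_RADIUS = 0.8


def planar_layout(graph: MolecularGraph) -> dict[int, tuple[float, float]]:
    """2-D coordinates from the ring/site labels; purely for visual export."""
    import math

    coords = {}
    for vid in range(graph.n_vertices):
        label = graph.labels.get(vid)
        if not (isinstance(label, tuple) and len(label) == 3):
            raise ValueError("planar_layout needs ring/site labels from a ribbon build")
        i, j, site = label
        cx = 3.0 * (j + i / 2.0)
        cy = 3.0 * i * math.sqrt(3) / 2.0
        ang = math.radians(60 * site - 30)  # site between its bridge direction's edge pair
        coords[vid] = (cx + _RING_RADIUS * math.cos(ang), cy + _RING_RADIUS * math.sin(ang))
    return coords


def to_xyz(graph: MolecularGraph) -> str:
    """All-carbon XYZ block with the cosmetic planar layout."""
    coords = planar_layout(graph)
    lines = [str(graph.n_vertices), "contracted-bridge graphyne ribbon (planar layout)"]
    for v in range(graph.n_vertices):
        x, y = coords[v]
        lines.append(f"C {x:12.6f} {y:12.6f} {0.0:12.6f}")
    return "\n".join(lines) + "\n"


def to_mol_block(graph: MolecularGraph) -> str:
    """Minimal MOL V2000 block (all atoms carbon, all bonds single order)."""
    coords = planar_layout(graph)
    lines = [
        "ribbon",
        "  leapdeg",
        "",
        f"{graph.n_vertices:3d}{graph.n_edges:3d}  0  0  0  0  0  0  0  0999 V2000",
    ]
    for v in range(graph.n_vertices):
        x, y = coords[v]
        lines.append(f"{x:10.4f}{y:10.4f}{0.0:10.4f} C   0  0  0  0  0  0  0  0  0  0  0  0")
    for u, v in sorted(graph.edges):
        lines.append(f"{u + 1:3d}{v + 1:3d}  1  0  0  0  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"
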