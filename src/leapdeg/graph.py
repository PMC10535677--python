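"""Graph substrate for distance-degree descriptors.

A molecular graph here is an undirected simple graph: atoms are vertices,
covalent bonds are edges, and bond multiplicity is ignored.  Everything in
this package is driven by the *k*-distance degree ``deg_k(v)``: the number of
vertices at shortest-path distance exactly *k* from *v* (``k = 1`` recovers
the ordinary degree).  Edges are then classified by the unordered pair of
endpoint ``deg_k`` values — the "edge partition technique" that turns an
index into a small weighted sum over partition classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "MolecularGraph",
    "KDegreeVector",
    "EdgePartition",
    "shortest_path_distances",
    "k_distance_degrees",
    "k_distance_degrees_oracle",
    "edge_partition",
    "fixture_graph",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class MolecularGraph:
    """Undirected simple graph on vertices ``0 .. n_vertices-1``.

    ``edges`` is a frozenset of ``(u, v)`` tuples with ``u < v``.  ``labels``
    optionally records provenance per vertex (e.g. ring row/column and hexagon
    site for generated nanoribbons); it carries no semantic weight.
    """

    n_vertices: int
    edges: frozenset[tuple[int, int]]
    labels: Mapping[int, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.n_vertices < 1:
            raise ValueError("graph must have at least one vertex")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
            if not (0 <= u < v < self.n_vertices):
                raise ValueError(f"edge ({u}, {v}) has an invalid endpoint")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @classmethod
    def from_edges(
        cls,
        n_vertices: int,
        edges: Iterable[tuple[int, int]],
        labels: Mapping[int, object] | None = None,
    ) -> "MolecularGraph":
        canon = frozenset((min(u, v), max(u, v)) for u, v in edges)
        return cls(n_vertices, canon, labels or {})

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "MolecularGraph":
        """Relabel an arbitrary networkx graph onto contiguous integer ids."""
        nodes = sorted(g.nodes(), key=str)
        idx = {node: i for i, node in enumerate(nodes)}
        edges = ((idx[u], idx[v]) for u, v in g.edges())
        return cls.from_edges(len(nodes), edges, labels={i: n for n, i in idx.items()})

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.edges)
        return g

    def degree_sequence(self) -> list[int]:
        deg = [0] * self.n_vertices
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg


@dataclass(frozen=True)
class KDegreeVector:
    """Per-vertex count of vertices at exactly distance ``k``."""

    k: int
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")

    def __getitem__(self, v: int) -> int:
        return self.values[v]

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class EdgePartition:
    """Multiset of unordered endpoint ``deg_k`` pairs over the edges of a graph.

    ``classes`` maps ``(a, b)`` with ``a <= b`` to the number of edges whose
    endpoints have ``deg_k`` values ``{a, b}``; counts sum to ``|E|``.
    """

    k: int
    classes: Mapping[tuple[int, int], int]

    def __post_init__(self) -> None:
        for (a, b), count in self.classes.items():
            if not (0 <= a <= b):
                raise ValueError(f"malformed class key ({a}, {b})")
            if count < 1:
                raise ValueError(f"class ({a}, {b}) has non-positive count")

    @property
    def n_edges(self) -> int:
        return sum(self.classes.values())

    def as_sorted_items(self) -> list[tuple[tuple[int, int], int]]:
        return sorted(self.classes.items())


def shortest_path_distances(graph: MolecularGraph, source: int) -> dict[int, int]:
    """Unweighted shortest-path (BFS) distances from ``source``.

    Unreachable vertices are simply absent from the returned mapping — no
    finite sentinel is ever used.
    """
    if not (0 <= source < graph.n_vertices):
        raise ValueError(f"invalid source vertex {source}")
    return dict(nx.single_source_shortest_path_length(graph.to_networkx(), source))


def k_distance_degrees(graph: MolecularGraph, k: int) -> KDegreeVector:
    """``deg_k(v)`` for every vertex, by one depth-limited BFS per vertex."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    g = graph.to_networkx()
    values = []
    for v in range(graph.n_vertices):
        dist = nx.single_source_shortest_path_length(g, v, cutoff=k)
        values.append(sum(1 for d in dist.values() if d == k))
    return KDegreeVector(k, tuple(values))


def k_distance_degrees_oracle(graph: MolecularGraph) -> KDegreeVector:
    """Independent ``deg_2`` oracle via the boolean square of the adjacency matrix.

    ``u`` counts toward ``deg_2(v)`` iff ``(A^2)_{uv} > 0``, ``A_{uv} = 0``
    and ``u != v``.  Exists purely to cross-check the BFS route.
    """
    n = graph.n_vertices
    a = np.zeros((n, n), dtype=bool)
    for u, v in graph.edges:
        a[u, v] = a[v, u] = True
    two_walk = (a.astype(np.int64) @ a.astype(np.int64)) > 0
    at_two = two_walk & ~a & ~np.eye(n, dtype=bool)
    return KDegreeVector(2, tuple(int(x) for x in at_two.sum(axis=1)))


def edge_partition(graph: MolecularGraph, k: int = 2) -> EdgePartition:
    """Group edges by the unordered pair of endpoint ``deg_k`` values."""
    degk = k_distance_degrees(graph, k)
    tally: Counter[tuple[int, int]] = Counter()
    for u, v in graph.edges:
        a, b = degk[u], degk[v]
        tally[(min(a, b), max(a, b))] += 1
    return EdgePartition(k, dict(tally))


_FIXTURE_KINDS = ("path", "cycle", "star", "complete", "random")


def fixture_graph(kind: str, size: int, seed: int | None = None) -> MolecularGraph:
    """Deterministic small test graphs.

    ``size`` is the vertex count; ``star`` with size ``s`` is K_{1,s-1}.
    ``random`` is an Erdos–Renyi G(n, 0.2) draw and requires a seed.
    """
    if kind not in _FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {_FIXTURE_KINDS}")
    if size < 1:
        raise ValueError("size must be >= 1")
    if kind == "path":
        g = nx.path_graph(size)
    elif kind == "cycle":
        if size < 3:
            raise ValueError("cycle needs at least 3 vertices")
        g = nx.cycle_graph(size)
    elif kind == "star":
        if size < 2:
            raise ValueError("star needs at least 2 vertices")
        g = nx.star_graph(size - 1)
    elif kind == "complete":
        g = nx.complete_graph(size)
    else:
        if seed is None:
            raise ValueError("random fixture requires a seed")
        g = nx.gnp_random_graph(size, 0.2, seed=seed)
    return MolecularGraph.from_edges(size, g.edges())


def read_edge_list(path) -> MolecularGraph:
    """Read the whitespace-delimited edge-list format.

    One edge per line as two labels; a single label declares an isolated
    vertex; ``#`` starts a comment.  Labels are arbitrary strings mapped to
    contiguous integer ids in sorted label order.
    """
    labels: set[str] = set()
    pairs: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) == 1:
                labels.add(parts[0])
            elif len(parts) == 2:
                if parts[0] == parts[1]:
                    raise ValueError(f"{path}:{lineno}: self-loop on {parts[0]!r}")
                labels.update(parts)
                pairs.append((parts[0], parts[1], lineno))
            else:
                raise ValueError(f"{path}:{lineno}: expected 1 or 2 labels, got {len(parts)}")
    if not labels:
        raise ValueError(f"{path}: no vertices declared")
    idx = {lab: i for i, lab in enumerate(sorted(labels))}
    edges = [(idx[a], idx[b]) for a, b, _ in pairs]
    return MolecularGraph.from_edges(len(idx), edges, labels={i: lab for lab, i in idx.items()})


def write_edge_list(graph: MolecularGraph, path, header: str | None = None) -> None:
    """Write sorted, deterministic edge-list output (isolated vertices included)."""
    touched = {u for e in graph.edges for u in e}
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for u, v in sorted(graph.edges):
            fh.write(f"{u} {v}\n")
        for v in range(graph.n_vertices):
            if v not in touched:
                fh.write(f"{v}\n")
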