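"""The ten leap-type topological indices.

All are sums over edges of a weight built from the endpoint 2-distance
degrees ``a = deg2(u)``, ``b = deg2(v)``:

=========  =============================
lm1        a + b              (first leap Zagreb)
lm2        a * b              (second leap Zagreb)
hlm1       (a + b)^2          (first hyper leap Zagreb)
hlm2       (a * b)^2          (second hyper leap Zagreb)
lgo1       (a + b) + (a * b)  (first leap gourava)
lgo2       (a + b) * (a * b)  (second leap gourava)
hlgo1      ((a + b) + (a * b))^2
hlgo2      ((a + b) * (a * b))^2
slgo       1 / sqrt((a + b) + (a * b))  (sum-connectivity leap gourava)
plgo       1 / sqrt((a + b) * (a * b))  (product-connectivity leap gourava)
=========  =============================

Given an :class:`~leapdeg.graph.EdgePartition` the sum collapses to a weighted
sum over partition classes.  The eight polynomial indices are evaluated in
exact (arbitrary-precision) integer arithmetic; the two connectivity indices
default to floating point with an opt-in exact symbolic mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import sympy

from .graph import EdgePartition, MolecularGraph, edge_partition

__all__ = [
    "INDEX_IDS",
    "INTEGER_INDEX_IDS",
    "IndexSuiteResult",
    "lm1", "lm2", "hlm1", "hlm2",
    "lgo1", "lgo2", "hlgo1", "hlgo2",
    "slgo", "plgo",
    "index_from_partition",
    "compute_indices",
]

#: canonical identifiers, in defining-equation order
INDEX_IDS = ("lm1", "lm2", "hlm1", "hlm2", "lgo1", "lgo2", "hlgo1", "hlgo2", "slgo", "plgo")
INTEGER_INDEX_IDS = INDEX_IDS[:8]

_INT_WEIGHTS: dict[str, Callable[[int, int], int]] = {
    "lm1": lambda a, b: a + b,
    "lm2": lambda a, b: a * b,
    "hlm1": lambda a, b: (a + b) ** 2,
    "hlm2": lambda a, b: (a * b) ** 2,
    "lgo1": lambda a, b: (a + b) + (a * b),
    "lgo2": lambda a, b: (a + b) * (a * b),
    "hlgo1": lambda a, b: ((a + b) + (a * b)) ** 2,
    "hlgo2": lambda a, b: ((a + b) * (a * b)) ** 2,
}

#: radicand of the per-edge weight of the two connectivity indices
_RADICANDS: dict[str, Callable[[int, int], int]] = {
    "slgo": lambda a, b: (a + b) + (a * b),
    "plgo": lambda a, b: (a + b) * (a * b),
}


def _check_nonempty(partition: EdgePartition) -> None:
    if not partition.classes:
        raise ValueError("empty edge partition")


def _integer_index(index_id: str, partition: EdgePartition) -> int:
    _check_nonempty(partition)
    w = _INT_WEIGHTS[index_id]
    return sum(count * w(a, b) for (a, b), count in partition.classes.items())


def _connectivity_index(index_id: str, partition: EdgePartition, exact: bool):
    _check_nonempty(partition)
    rad = _RADICANDS[index_id]
    total = sympy.Integer(0) if exact else 0.0
    for (a, b), count in partition.classes.items():
        r = rad(a, b)
        if r <= 0:
            raise ValueError(
                f"{index_id} undefined: class ({a}, {b}) has non-positive "
                f"weight denominator {r}"
            )
        if exact:
            total += count / sympy.sqrt(sympy.Integer(r))
        else:
            total += count / math.sqrt(r)
    return total


def lm1(partition: EdgePartition) -> int:
    """First leap Zagreb index: sum of ``deg2(u) + deg2(v)`` over edges."""
    return _integer_index("lm1", partition)


def lm2(partition: EdgePartition) -> int:
    """Second leap Zagreb index: sum of ``deg2(u) * deg2(v)`` over edges."""
    return _integer_index("lm2", partition)


def hlm1(partition: EdgePartition) -> int:
    """First hyper leap Zagreb index: sum of ``(deg2(u) + deg2(v))^2``."""
    return _integer_index("hlm1", partition)


def hlm2(partition: EdgePartition) -> int:
    """Second hyper leap Zagreb index: sum of ``(deg2(u) * deg2(v))^2``."""
    return _integer_index("hlm2", partition)


def lgo1(partition: EdgePartition) -> int:
    """First leap gourava index: sum of ``(a + b) + (a * b)``."""
    return _integer_index("lgo1", partition)


def lgo2(partition: EdgePartition) -> int:
    """Second leap gourava index: sum of ``(a + b) * (a * b)``."""
    return _integer_index("lgo2", partition)


def hlgo1(partition: EdgePartition) -> int:
    """First hyper leap gourava index: sum of ``((a + b) + (a * b))^2``."""
    return _integer_index("hlgo1", partition)


def hlgo2(partition: EdgePartition) -> int:
    """Second hyper leap gourava index: sum of ``((a + b) * (a * b))^2``."""
    return _integer_index("hlgo2", partition)


def slgo(partition: EdgePartition, exact: bool = False):
    """Sum-connectivity leap gourava index: sum of ``1/sqrt((a+b)+(a*b))``.

    Raises ``ValueError`` for any class whose denominator is not positive
    (e.g. both endpoints with ``deg2 = 0``); with ``exact=True`` returns a
    sympy expression instead of a float.
    """
    return _connectivity_index("slgo", partition, exact)


def plgo(partition: EdgePartition, exact: bool = False):
    """Product-connectivity leap gourava index: sum of ``1/sqrt((a+b)*(a*b))``."""
    return _connectivity_index("plgo", partition, exact)


_DISPATCH: dict[str, Callable] = {
    "lm1": lm1, "lm2": lm2, "hlm1": hlm1, "hlm2": hlm2,
    "lgo1": lgo1, "lgo2": lgo2, "hlgo1": hlgo1, "hlgo2": hlgo2,
    "slgo": slgo, "plgo": plgo,
}


def index_from_partition(index_id: str, partition: EdgePartition):
    """Evaluate one index by its lowercase identifier."""
    try:
        fn = _DISPATCH[index_id]
    except KeyError:
        raise ValueError(f"unknown index {index_id!r}; expected one of {INDEX_IDS}") from None
    return fn(partition)


@dataclass(frozen=True)
class IndexSuiteResult:
    """Values of all ten indices for one graph (or partition)."""

    lm1: int
    lm2: int
    hlm1: int
    hlm2: int
    lgo1: int
    lgo2: int
    hlgo1: int
    hlgo2: int
    slgo: float
    plgo: float
    provenance: str = "from_graph"

    def __getitem__(self, index_id: str):
        if index_id not in INDEX_IDS:
            raise KeyError(index_id)
        return getattr(self, index_id)

    def as_dict(self) -> dict[str, float | int]:
        return {name: getattr(self, name) for name in INDEX_IDS}


def compute_indices(
    source: MolecularGraph | EdgePartition, k: int = 2
) -> IndexSuiteResult:
    """All ten indices from a graph (partition extracted at distance ``k``)
    or directly from a pre-computed partition."""
    if isinstance(source, MolecularGraph):
        partition = edge_partition(source, k)
        provenance = "from_graph"
    else:
        partition = source
        provenance = "from_partition"
    values = {name: _integer_index(name, partition) for name in INTEGER_INDEX_IDS}
    return IndexSuiteResult(
        **values,
        slgo=slgo(partition),
        plgo=plgo(partition),
        provenance=provenance,
    )
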