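"""Open-triangle (induced two-path) enumeration.

An open triangle is a trio where a central *common* protein interacts with
two partners V1 and V2 that do not interact with each other; the common node
is unique per trio, so every open triangle corresponds to exactly one
:class:`Triplet`.  At interactome scale there are tens of millions of these,
hence the streaming iterator next to the set-returning enumerator.
"""

from __future__ import annotations

from math import comb
from typing import Iterator, NamedTuple

import networkx as nx

__all__ = ["Triplet", "iter_open_triangles", "enumerate_open_triangles", "count_open_triangles"]


class Triplet(NamedTuple):
    """An open triangle, stored with canonical partner order v1 < v2."""

    common: str
    v1: str
    v2: str

    @classmethod
    def make(cls, common: str, u: str, w: str) -> "Triplet":
        return cls(common, u, w) if u < w else cls(common, w, u)


def iter_open_triangles(net: nx.Graph) -> Iterator[Triplet]:
    """Yield every open triangle exactly once, in bounded memory.

    For each node c, every unordered neighbour pair {u, w} with u–w not an
    edge yields ``Triplet(c, u, w)``; distinct common nodes guarantee no
    duplicates across centres.
    """
    for c in sorted(net.nodes()):
        nbrs = sorted(net.neighbors(c))
        for i, u in enumerate(nbrs):
            u_adj = net[u]
            for w in nbrs[i + 1 :]:
                if w not in u_adj:
                    yield Triplet(c, u, w)


def enumerate_open_triangles(net: nx.Graph) -> set[Triplet]:
    """All open triangles as a set (materialises; use the iterator at scale)."""
    return set(iter_open_triangles(net))


def count_open_triangles(net: nx.Graph) -> int:
    """Closed-form count: sum_v C(deg v, 2) minus 3 per closed triangle.

    Each triangle is counted once per corner as a two-path, so subtracting
    three per triangle leaves exactly the induced (open) two-paths.  Serves
    as an independent oracle for the enumerator.
    """
    wedges = sum(comb(d, 2) for _, d in net.degree())
    n_triangles = sum(nx.triangles(net).values()) // 3
    return wedges - 3 * n_triangles
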