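"""Scored edge lists, high-confidence network construction, and centralities.

The interaction network is an undirected simple :class:`networkx.Graph` whose
nodes are opaque protein identifiers (UniProt accessions in real data).
Construction follows the standard recipe for confidence-scored interaction
databases: threshold on the score, drop self-interactions, collapse duplicate
rows, and keep the largest connected component.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, TextIO

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ScoredEdge",
    "load_scored_edges",
    "build_network",
    "largest_connected_component",
    "compute_centralities",
    "write_edge_list",
]

DEFAULT_MIN_SCORE = 0.71


@dataclass(frozen=True)
class ScoredEdge:
    """One row of a scored edge list: two proteins and a confidence in [0, 1]."""

    protein_a: str
    protein_b: str
    confidence: float

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise ValueError("protein identifiers must be non-empty")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


def load_scored_edges(
    source: str | TextIO,
    columns: tuple[str, str, str] = ("protein_a", "protein_b", "confidence"),
) -> list[ScoredEdge]:
    """Read a scored edge list from a TSV file or stream.

    The file must carry a header naming the three ``columns``; lines starting
    with ``#`` are ignored.  Row order is preserved.  A malformed row or a
    confidence outside [0, 1] raises :class:`ValueError` naming the line.
    """
    df = _read_tsv(source, required=columns)
    edges = []
    for idx, row in enumerate(df.itertuples(index=False)):
        a, b = str(getattr(row, columns[0])), str(getattr(row, columns[1]))
        raw = getattr(row, columns[2])
        try:
            conf = float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"line {idx + 2}: confidence {raw!r} is not a number") from None
        if np.isnan(conf) or not 0.0 <= conf <= 1.0:
            raise ValueError(f"line {idx + 2}: confidence {raw!r} outside [0, 1]")
        edges.append(ScoredEdge(a, b, conf))
    return edges


def _read_tsv(source: str | TextIO, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    if df[list(required[:2])].isna().any().any():
        bad = int(df[list(required[:2])].isna().any(axis=1).idxmax())
        raise ValueError(f"line {bad + 2}: malformed row (missing field)")
    return df


def build_network(edges: Iterable[ScoredEdge], min_score: float = DEFAULT_MIN_SCORE) -> nx.Graph:
    """Build the high-confidence interaction network from scored edges.

    Keeps edges with ``confidence >= min_score`` (inclusive), removes
    self-interactions, and collapses duplicates in either orientation into a
    single undirected edge.  Conflicting duplicate scores resolve to the
    maximum before thresholding.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score must be in [0, 1], got {min_score}")
    best: dict[tuple[str, str], float] = {}
    for e in edges:
        if e.protein_a == e.protein_b:
            continue
        key = (e.protein_a, e.protein_b) if e.protein_a < e.protein_b else (e.protein_b, e.protein_a)
        prev = best.get(key)
        if prev is None or e.confidence > prev:
            best[key] = e.confidence
    g = nx.Graph()
    for (a, b), conf in best.items():
        if conf >= min_score:
            g.add_edge(a, b, confidence=conf)
    return g


def largest_connected_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties between equally sized components are broken by the lexicographically
    smallest member identifier, for determinism.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot take the largest component of an empty network")
    comps = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    return net.subgraph(comps[0]).copy()


def compute_centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree, closeness, betweenness and eigenvector centrality per node.

    DC is the raw integer degree (the low-degree filter downstream reads
    naturally on raw degree).  CC is the standard ``(n-1)/sum of distances``;
    BC is pair-normalised; EC is the principal adjacency eigenvector scaled to
    a maximum of 1.  Requires a connected network: closeness is undefined
    across components.
    """
    if net.number_of_nodes() == 0 or not nx.is_connected(net):
        raise ValueError("centralities require a non-empty connected network (run LCC first)")
    nodes = sorted(net.nodes())
    dc = dict(net.degree())
    cc = nx.closeness_centrality(net)
    bc = nx.betweenness_centrality(net, normalized=True)
    if net.number_of_nodes() >= 3:
        ec = nx.eigenvector_centrality_numpy(net)
    else:  # trivial graphs: uniform principal eigenvector
        ec = {v: 1.0 for v in nodes}
    ec_max = max(abs(x) for x in ec.values())
    table = pd.DataFrame(
        {
            "DC": [dc[v] for v in nodes],
            "CC": [cc[v] for v in nodes],
            "BC": [bc[v] for v in nodes],
            "EC": [abs(ec[v]) / ec_max for v in nodes],
        },
        index=pd.Index(nodes, name="protein"),
    )
    table["DC"] = table["DC"].astype(int)
    return table


def write_edge_list(net: nx.Graph, path: str | io.TextIOBase) -> None:
    """Serialise a network as a canonical edge-list TSV (smaller id first)."""
    rows = sorted(tuple(sorted(e)) for e in net.edges())
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b"])
    df["confidence"] = [net.edges[e].get("confidence", 1.0) for e in rows]
    df.to_csv(path, sep="\t", index=False)
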