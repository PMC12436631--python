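"""Deriving the cooperative (positive) class from structural complex records.

Complexes resolved as multi-protein structures report which member pairs are
in physical contact.  A trio inside a complex with exactly two of its three
possible pairwise contacts is a cooperative triplet: both partners bind the
shared member simultaneously, at what must be distinct interfaces.  Trios
with all three contacts have no unique centre and trios with one contact are
not triangles at all; both are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, TextIO

import networkx as nx
import pandas as pd

from .triplets import Triplet

__all__ = [
    "ComplexRecord",
    "CooperativeLabelSet",
    "load_complex_interactions",
    "extract_structural_triplets",
    "map_to_network",
    "deduplicate_by_common",
]


@dataclass
class ComplexRecord:
    """A structural complex: its members and the observed pairwise contacts."""

    complex_id: str
    members: set[str] = field(default_factory=set)
    observed_pairs: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for pair in self.observed_pairs:
            if len(pair) != 2:
                raise ValueError(f"{self.complex_id}: self-pair or malformed pair {set(pair)}")
            if not pair <= self.members:
                raise ValueError(f"{self.complex_id}: pair {set(pair)} outside member set")


@dataclass
class CooperativeLabelSet:
    """Ordered cooperative triplets plus which complexes support each one."""

    triplets: list[Triplet]
    provenance: dict[Triplet, list[str]]


def load_complex_interactions(source: str | TextIO) -> list[ComplexRecord]:
    """Read a complex-interaction TSV into grouped :class:`ComplexRecord` s.

    Expected columns: ``complex_id, protein_1, protein_2, evidence``.  Rows
    with model-based evidence and self-pairs are dropped; complexes are kept
    in first-appearance order and only those with at least 3 distinct members
    survive.
    """
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    required = ["complex_id", "protein_1", "protein_2", "evidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    records: dict[str, ComplexRecord] = {}
    for idx, row in df.iterrows():
        cid, p1, p2, ev = (row[c] for c in required)
        if pd.isna(cid) or pd.isna(p1) or pd.isna(p2) or pd.isna(ev):
            raise ValueError(f"line {idx + 2}: malformed row (missing field)")
        rec = records.setdefault(str(cid), ComplexRecord(str(cid)))
        if ev == "model" or p1 == p2:
            continue
        rec.members.update((str(p1), str(p2)))
        rec.observed_pairs.add(frozenset((str(p1), str(p2))))
    return [r for r in records.values() if len(r.members) >= 3]


def extract_structural_triplets(complexes: Iterable[ComplexRecord]) -> list[Triplet]:
    """Exactly-two-of-three rule: every complex trio with 2 observed contacts.

    The triplet's common interactor is the member present in both contacts.
    Output order is complex order, then lexicographic trio order — the
    dataset order the downstream one-per-common deduplication relies on.
    """
    out: list[Triplet] = []
    for rec in complexes:
        for trio in combinations(sorted(rec.members), 3):
            pairs = [frozenset(p) for p in combinations(trio, 2)]
            present = [p for p in pairs if p in rec.observed_pairs]
            if len(present) != 2:
                continue
            (common,) = set.intersection(*map(set, present))
            v1, v2 = sorted(set(trio) - {common})
            out.append(Triplet(common, v1, v2))
    return out


def map_to_network(struct: Iterable[Triplet], net: nx.Graph) -> list[Triplet]:
    """Keep structural triplets that are open triangles of the network.

    Requires common–v1 and common–v2 to be network edges and v1–v2 to be a
    non-edge; order is preserved.  Trios closed in the network (all three
    edges present) are discarded: they have no unique centre there.
    """
    out = []
    for t in struct:
        if (
            net.has_edge(t.common, t.v1)
            and net.has_edge(t.common, t.v2)
            and not net.has_edge(t.v1, t.v2)
        ):
            out.append(t)
    return out


def deduplicate_by_common(
    triplets: Iterable[Triplet],
    provenance: dict[Triplet, list[str]] | None = None,
) -> CooperativeLabelSet:
    """One triplet per common interactor: first occurrence in dataset order wins.

    Large assemblies (ribosomes, proteasomes) otherwise flood the positive
    class with near-duplicate trios sharing a centre.
    """
    seen: set[str] = set()
    kept: list[Triplet] = []
    for t in triplets:
        if t.common not in seen:
            seen.add(t.common)
            kept.append(t)
    prov = {t: (provenance or {}).get(t, []) for t in kept}
    return CooperativeLabelSet(triplets=kept, provenance=prov)


def structural_provenance(complexes: Iterable[ComplexRecord]) -> dict[Triplet, list[str]]:
    """Map each exactly-two trio to every complex id that supports it."""
    prov: dict[Triplet, list[str]] = {}
    for rec in complexes:
        for t in extract_structural_triplets([rec]):
            prov.setdefault(t, []).append(rec.complex_id)
    return prov
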