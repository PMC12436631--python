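"""Synthetic inputs with the statistical structure the pipeline assumes.

Everything downstream of the raw databases can be exercised on data built
here: a popularity–similarity (PS) network grown with known ground-truth
hyperbolic coordinates, structural complex tables that induce known
cooperative triplets, protein annotation and paralog tables with
configurable frequencies, and a planted-signal triplet dataset in which the
positive class has systematically smaller V1–V2 angular separation — the
signal the classifier is expected to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .complexes import ComplexRecord
from .embedding import EmbeddedNetwork
from .geometry import PSModelParams, angular_separation, connection_probability
from .triplets import Triplet, iter_open_triangles

__all__ = [
    "SyntheticBundle",
    "ps_generate",
    "synth_complex_table",
    "synth_annotations",
    "plant_signal_dataset",
    "synth_paralog_pairs",
    "make_bundle",
    "write_complex_table",
    "write_annotation_table",
    "write_paralog_table",
]

from .features import LOCALIZATIONS


def _node_name(t: int) -> str:
    return f"P{t:06d}"  # birth order == lexicographic order


def ps_generate(params: PSModelParams, n: int, seed: int) -> EmbeddedNetwork:
    """Grow a PS-model network of ``n`` nodes; coordinates are ground truth.

    Node t (t = 1..n) appears at angle uniform in ``[0, angular_span)`` and
    birth radius ``2 ln t``; earlier nodes fade outward to
    ``2 beta ln s + 2 (1 - beta) ln t``.  The newcomer links to
    ``min(m, t-1)`` existing nodes — the hyperbolically nearest at T = 0,
    otherwise sampled without replacement with Fermi–Dirac weights at cutoff
    ``R_t = r_t``.  Returned coordinates are the faded positions at t = n.
    The edge count is exactly ``sum_t min(m, t-1)`` for every seed.
    """
    if n < params.m + 1:
        raise ValueError(f"need n >= m + 1 = {params.m + 1}, got {n}")
    rng = np.random.default_rng(seed)
    beta, m, T = params.beta, params.m, params.temperature
    theta = rng.uniform(0.0, params.angular_span, size=n)
    births = 2.0 * np.log(np.arange(1, n + 1))
    g = nx.Graph()
    g.add_node(_node_name(1))
    for t in range(2, n + 1):
        i = t - 1  # 0-based index of the newcomer
        r_t = births[i]
        s = np.arange(1, t)
        r_faded = 2.0 * beta * np.log(s) + 2.0 * (1.0 - beta) * np.log(t)
        dtheta = angular_separation(theta[i], theta[:i])
        arg = np.cosh(r_t) * np.cosh(r_faded) - np.sinh(r_t) * np.sinh(r_faded) * np.cos(dtheta)
        d = np.arccosh(np.maximum(arg, 1.0))
        k = min(m, t - 1)
        if T == 0:
            # nearest-first, ties by birth order for determinism
            targets = np.lexsort((s, d))[:k]
        else:
            w = connection_probability(d, r_t, T)
            w = np.asarray(w, dtype=float) + 1e-300  # keep every node reachable
            targets = rng.choice(i, size=k, replace=False, p=w / w.sum())
        for j in targets:
            g.add_edge(_node_name(t), _node_name(int(j) + 1))
    final_r = 2.0 * beta * np.log(np.arange(1, n + 1)) + 2.0 * (1.0 - beta) * np.log(n)
    coords = pd.DataFrame(
        {"r": final_r, "theta": theta % (2 * np.pi)},
        index=pd.Index([_node_name(t) for t in range(1, n + 1)], name="protein"),
    )
    return EmbeddedNetwork(graph=g, coords=coords, params=params)


def synth_complex_table(
    emb: EmbeddedNetwork,
    n_complexes: int,
    size_range: tuple[int, int] = (3, 8),
    seed: int = 0,
    p_observe: float = 0.8,
) -> tuple[list[ComplexRecord], list[Triplet]]:
    """Structural complex records plus the cooperative truth they induce.

    Each complex is a connected node subset (grown by random breadth-first
    expansion); each within-complex network edge is reported as an observed
    pairwise contact with probability ``p_observe``, producing a mixture of
    exactly-two trios (cooperative truth), all-three trios and one-contact
    trios.  The truth list holds every member trio with exactly two observed
    contacts whose missing pair is also a network non-edge, i.e. exactly the
    open triangles of the network a structural labeler should recover before
    deduplication.
    """
    lo, hi = size_range
    if lo < 3 or hi < lo:
        raise ValueError(f"size_range must satisfy 3 <= min <= max, got {size_range}")
    if emb.graph.number_of_nodes() < hi:
        raise ValueError("network smaller than the largest requested complex")
    rng = np.random.default_rng(seed)
    nodes = sorted(emb.graph.nodes())
    records: list[ComplexRecord] = []
    truth: list[Triplet] = []
    for c in range(n_complexes):
        size = int(rng.integers(lo, hi + 1))
        start = nodes[int(rng.integers(len(nodes)))]
        members = _connected_subset(emb.graph, start, size, rng)
        inner_edges = [
            frozenset((u, v))
            for u, v in emb.graph.subgraph(members).edges()
        ]
        observed = {e for e in inner_edges if rng.random() < p_observe}
        obs_members = sorted({p for e in observed for p in e})
        if len(obs_members) < 3:
            continue
        rec = ComplexRecord(
            complex_id=f"CPX{c:04d}",
            members=set(obs_members),
            observed_pairs=observed,
        )
        records.append(rec)
        truth.extend(_trio_truth(rec, emb.graph))
    return records, truth


def _connected_subset(g: nx.Graph, start: str, size: int, rng: np.random.Generator) -> list[str]:
    chosen = [start]
    frontier = sorted(g.neighbors(start))
    seen = {start}
    while len(chosen) < size and frontier:
        pick = frontier.pop(int(rng.integers(len(frontier))))
        if pick in seen:
            continue
        seen.add(pick)
        chosen.append(pick)
        frontier.extend(v for v in sorted(g.neighbors(pick)) if v not in seen)
    return chosen


def _trio_truth(rec: ComplexRecord, g: nx.Graph) -> list[Triplet]:
    """Brute-force exactly-two-of-three scan; independent of the labeler code."""
    from itertools import combinations

    out = []
    for trio in combinations(sorted(rec.members), 3):
        pairs = [frozenset(p) for p in combinations(trio, 2)]
        present = [p for p in pairs if p in rec.observed_pairs]
        if len(present) != 2:
            continue
        (common,) = set.intersection(*map(set, present))
        v1, v2 = sorted(set(trio) - {common})
        if g.has_edge(common, v1) and g.has_edge(common, v2) and not g.has_edge(v1, v2):
            out.append(Triplet(common, v1, v2))
    return out


def synth_annotations(
    nodes: Sequence[str],
    p_idr: float = 0.3,
    loc_probs: Sequence[float] = (0.30, 0.30, 0.15, 0.10),
    seed: int = 0,
) -> pd.DataFrame:
    """Random IDR flags and subcellular localizations with given frequencies.

    ``loc_probs`` gives the probabilities of (nucleus, cytoplasm,
    endomembrane, multi_localized); the remainder to 1 is left unannotated.
    """
    if not 0.0 <= p_idr <= 1.0:
        raise ValueError(f"p_idr must be in [0, 1], got {p_idr}")
    loc_probs = np.asarray(loc_probs, dtype=float)
    if loc_probs.shape != (4,) or (loc_probs < 0).any() or loc_probs.sum() > 1 + 1e-12:
        raise ValueError("loc_probs must be 4 nonnegative values summing to <= 1")
    rng = np.random.default_rng(seed)
    nodes = sorted(set(nodes))
    idr = (rng.random(len(nodes)) < p_idr).astype(int)
    cats = list(LOCALIZATIONS) + ["unannotated"]
    p = np.append(loc_probs, 1.0 - loc_probs.sum())
    loc = rng.choice(len(cats), size=len(nodes), p=p / p.sum())
    return pd.DataFrame(
        {"idr": idr, "localization": [cats[i] for i in loc]},
        index=pd.Index(nodes, name="protein"),
    )


def plant_signal_dataset(
    emb: EmbeddedNetwork,
    n_pos: int,
    n_neg: int,
    theta_gap: float = 0.25,
    seed: int = 0,
) -> list[tuple[Triplet, str]]:
    """Labeled open triangles with a planted V1–V2 angular-separation signal.

    Open triangles whose V1–V2 angular separation lies below the
    ``theta_gap`` quantile form the cooperative pool, those above it the
    competitive pool; ``n_pos`` and ``n_neg`` disjoint triplets are sampled
    from the pools.  By construction the mean separation over positives is
    below that over negatives — the dominant-feature structure the
    classifier is meant to pick up.
    """
    triplets = list(iter_open_triangles(emb.graph))
    if not triplets:
        raise ValueError("network has no open triangles")
    theta = emb.coords["theta"]
    td = np.array([angular_separation(theta[t.v1], theta[t.v2]) for t in triplets])
    cut = np.quantile(td, theta_gap)
    pos_pool = [t for t, x in zip(triplets, td) if x < cut]
    neg_pool = [t for t, x in zip(triplets, td) if x > cut]
    if len(pos_pool) < n_pos or len(neg_pool) < n_neg:
        raise ValueError(
            f"insufficient open triangles: pools {len(pos_pool)}/{len(neg_pool)}, "
            f"requested {n_pos}/{n_neg}"
        )
    rng = np.random.default_rng(seed)
    pos = [pos_pool[i] for i in rng.choice(len(pos_pool), size=n_pos, replace=False)]
    neg = [neg_pool[i] for i in rng.choice(len(neg_pool), size=n_neg, replace=False)]
    return [(t, "cooperative") for t in pos] + [(t, "competitive") for t in neg]


def synth_paralog_pairs(
    nodes: Sequence[str],
    rate: float,
    emb: EmbeddedNetwork | None = None,
    bias_to_close_theta: bool = False,
    seed: int = 0,
    angular_scale: float = 0.3,
    candidate_pairs: Sequence[frozenset[str]] | None = None,
) -> set[frozenset[str]]:
    """Random unordered paralog pairs, optionally enriched at small angles.

    ``rate`` is pairs per node (``round(rate * n)`` pairs are drawn).  With
    the bias on, candidate pairs are selected with weight
    ``exp(-thetad / angular_scale)``, so paralogs cluster at small angular
    separations and interpretation-stage trends become recoverable.  By
    default candidates are random node pairs; passing ``candidate_pairs``
    (e.g. the V1–V2 pairs of a triplet universe) concentrates the annotation
    where downstream joins will look for it.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if bias_to_close_theta and emb is None:
        raise ValueError("bias_to_close_theta requires an embedding")
    nodes = sorted(set(nodes))
    n_pairs = round(rate * len(nodes))
    if n_pairs == 0:
        return set()
    rng = np.random.default_rng(seed)
    if candidate_pairs is not None:
        cand = sorted({frozenset(p) for p in candidate_pairs}, key=lambda p: tuple(sorted(p)))
    else:
        # oversample random pairs, then weight-select distinct ones
        n_cand = max(20 * n_pairs, 100)
        a = rng.integers(len(nodes), size=n_cand)
        b = rng.integers(len(nodes), size=n_cand)
        keep = a != b
        cand_set = {frozenset((nodes[i], nodes[j])) for i, j in zip(a[keep], b[keep])}
        cand = sorted(cand_set, key=lambda p: tuple(sorted(p)))
    if len(cand) < n_pairs:
        raise ValueError("too few distinct candidate pairs; raise rate or node count")
    if bias_to_close_theta:
        theta = emb.coords["theta"]
        td = np.array([angular_separation(theta[min(p)], theta[max(p)]) for p in cand])
        w = np.exp(-td / angular_scale)
    else:
        w = np.ones(len(cand))
    picks = rng.choice(len(cand), size=n_pairs, replace=False, p=w / w.sum())
    return {cand[i] for i in picks}


@dataclass
class SyntheticBundle:
    """Everything one pipeline run needs, with ground truth attached."""

    embedded: EmbeddedNetwork
    complexes: list[ComplexRecord]
    truth_triplets: list[Triplet]
    annotations: pd.DataFrame
    paralog_pairs: set[frozenset[str]]


def make_bundle(
    n: int = 1000,
    params: PSModelParams | None = None,
    n_complexes: int = 60,
    seed: int = 0,
) -> SyntheticBundle:
    """One-call synthetic study: network, complexes, annotations, paralogs."""
    params = params or PSModelParams()
    emb = ps_generate(params, n, seed)
    complexes, truth = synth_complex_table(emb, n_complexes, seed=seed + 1)
    ann = synth_annotations(list(emb.graph.nodes()), seed=seed + 2)
    # paralogy lives on V1-V2 partner pairs, so candidates come from the
    # open-triangle universe; genome-wide random pairs would almost never
    # coincide with any triplet's partner pair at desk scale
    candidates = {frozenset((t.v1, t.v2)) for t in iter_open_triangles(emb.graph)}
    paralogs = synth_paralog_pairs(
        list(emb.graph.nodes()),
        rate=0.2,
        emb=emb,
        bias_to_close_theta=True,
        seed=seed + 3,
        candidate_pairs=sorted(candidates, key=lambda p: tuple(sorted(p))),
    )
    return SyntheticBundle(emb, complexes, truth, ann, paralogs)


# ---------------------------------------------------------------------------
# writers for the TSV dialects the readers consume


def write_complex_table(records: Sequence[ComplexRecord], path) -> None:
    rows = []
    for rec in records:
        for pair in sorted(rec.observed_pairs, key=lambda p: tuple(sorted(p))):
            p1, p2 = sorted(pair)
            rows.append((rec.complex_id, p1, p2, "structure"))
    pd.DataFrame(rows, columns=["complex_id", "protein_1", "protein_2", "evidence"]).to_csv(
        path, sep="\t", index=False
    )


def write_annotation_table(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t")


def write_paralog_table(pairs: set[frozenset[str]], path) -> None:
    rows = sorted(tuple(sorted(p)) for p in pairs)
    pd.DataFrame(rows, columns=["protein_1", "protein_2"]).to_csv(path, sep="\t", index=False)


def write_truth_json(bundle: SyntheticBundle, path) -> None:
    payload = {
        "coordinates": {
            p: [float(r), float(t)]
            for p, r, t in bundle.embedded.coords.itertuples(index=True)
        },
        "cooperative_triplets": [list(t) for t in bundle.truth_triplets],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
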