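"""Post-hoc biological interpretation of triplet scores.

Mirrors the downstream reading of the classifier output: restrict to
triplets whose three proteins all have low degree (hubs otherwise dominate),
cut the scores into four rank-based quartiles, and ask how the fraction of
paralogous V1–V2 pairs and the V1–V2 angular separation move from the
competitive-like (Q1) to the cooperative-like (Q4) end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .embedding import EmbeddedNetwork
from .geometry import angular_separation

__all__ = [
    "filter_low_degree",
    "quartile_bins",
    "paralog_fraction_by_bin",
    "thetad_by_bin",
    "score_distribution_summary",
]

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


def filter_low_degree(
    scores: pd.DataFrame, cents: pd.DataFrame, max_degree: int = 10
) -> pd.DataFrame:
    """Keep triplets where common, V1 and V2 all have degree <= ``max_degree``."""
    for col in ("common", "v1", "v2"):
        missing = set(scores[col]) - set(cents.index)
        if missing:
            raise KeyError(f"no centrality row for: {sorted(missing)[:5]}")
    dc = cents["DC"]
    mask = (
        (scores["common"].map(dc) <= max_degree)
        & (scores["v1"].map(dc) <= max_degree)
        & (scores["v2"].map(dc) <= max_degree)
    )
    return scores[mask].reset_index(drop=True)


def quartile_bins(scores: pd.DataFrame) -> pd.Series:
    """Rank-based score quartiles; Q1 = lowest scores, Q4 = highest.

    Ties break by stable rank on the triplet key; bin sizes differ by at
    most one, with the remainder going to the lowest bins first (largest
    remainder to Q1).
    """
    n = len(scores)
    if n < 4:
        raise ValueError(f"need at least 4 scored triplets, got {n}")
    keys = [c for c in ("common", "v1", "v2") if c in scores.columns]
    order = scores.sort_values(["score", *keys], kind="stable").index
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    labels = np.empty(n, dtype=object)
    start = 0
    for q, size in zip(QUARTILES, sizes):
        labels[start : start + size] = q
        start += size
    return pd.Series(labels, index=order, name="quartile").reindex(scores.index)


def paralog_fraction_by_bin(
    scores: pd.DataFrame, bins: pd.Series, paralog_pairs: set[frozenset[str]]
) -> pd.DataFrame:
    """Per quartile: fraction of triplets whose {V1, V2} is a paralog pair."""
    is_para = [
        frozenset((v1, v2)) in paralog_pairs for v1, v2 in zip(scores["v1"], scores["v2"])
    ]
    df = pd.DataFrame({"quartile": bins.values, "paralog": is_para})
    out = df.groupby("quartile", sort=True).agg(n=("paralog", "size"), paralog_fraction=("paralog", "mean"))
    return out.reindex(QUARTILES)


def thetad_by_bin(scores: pd.DataFrame, bins: pd.Series, emb: EmbeddedNetwork) -> pd.DataFrame:
    """Per quartile: summary statistics of the V1–V2 angular separation."""
    theta = emb.coords["theta"]
    td = np.array(
        [angular_separation(theta[v1], theta[v2]) for v1, v2 in zip(scores["v1"], scores["v2"])]
    )
    df = pd.DataFrame({"quartile": bins.values, "thetad": td})
    out = df.groupby("quartile", sort=True)["thetad"].agg(
        n="size", mean="mean", median="median",
        q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75),
    )
    return out.reindex(QUARTILES)


def score_distribution_summary(score_sets: dict[str, np.ndarray], n_bins: int = 20) -> pd.DataFrame:
    """Fixed-width histogram over [0, 1] plus a five-number summary per set.

    Supports side-by-side comparison of e.g. all predictions, the training
    set, an external validation set and a low-degree subset.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for name, scores in score_sets.items():
        scores = np.asarray(scores, dtype=float)
        if scores.size == 0:
            raise ValueError(f"score set {name!r} is empty")
        hist, _ = np.histogram(scores, bins=edges)
        rows.append(
            {
                "set": name,
                "n": scores.size,
                "min": float(scores.min()),
                "q1": float(np.quantile(scores, 0.25)),
                "median": float(np.median(scores)),
                "q3": float(np.quantile(scores, 0.75)),
                "max": float(scores.max()),
                "histogram": hist.tolist(),
            }
        )
    return pd.DataFrame(rows).set_index("set")
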