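#!/usr/bin/env python
"""Biological interpretation of the triplet scores.

Restricts to triplets whose three proteins all have degree <= 10, cuts the
scores into quartiles (Q1 = competitive-like .. Q4 = cooperative-like), and
reports how the paralogous-V1/V2 fraction and the V1-V2 angular separation
move across quartiles, plus score-distribution summaries for the
all-predictions set, the positive training labels and the low-degree subset.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import coopnet as cn
from coopnet.embedding import read_coordinates
from coopnet.geometry import PSModelParams
from coopnet.network import build_network, largest_connected_component, load_scored_edges


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--edges", type=Path, default=Path("results/synthetic/edges.tsv"))
    ap.add_argument("--scores", type=Path, default=Path("results/model/scores.tsv"))
    ap.add_argument("--coords", type=Path, default=Path("results/embedding/coordinates.tsv"))
    ap.add_argument("--centralities", type=Path, default=Path("results/embedding/centralities.tsv"))
    ap.add_argument("--paralogs", type=Path, default=Path("results/synthetic/paralogs.tsv"))
    ap.add_argument("--labels", type=Path, default=Path("results/triplets/cooperative_labels.tsv"))
    ap.add_argument("--max-degree", type=int, default=10)
    ap.add_argument("--out", type=Path, default=Path("results/interpretation"))
    args = ap.parse_args()

    net = largest_connected_component(
        build_network(load_scored_edges(str(args.edges)), min_score=0.71)
    )
    emb = read_coordinates(args.coords, net, PSModelParams())
    cents = pd.read_csv(args.centralities, sep="\t", index_col="protein")
    scores = pd.read_csv(args.scores, sep="\t")
    para_df = pd.read_csv(args.paralogs, sep="\t")
    paralogs = {frozenset((a, b)) for a, b in para_df.itertuples(index=False)}

    low = cn.filter_low_degree(scores, cents, max_degree=args.max_degree)
    print(f"{len(low)} of {len(scores)} triplets have all degrees <= {args.max_degree}")
    bins = cn.quartile_bins(low)
    pf = cn.paralog_fraction_by_bin(low, bins, paralogs)
    td = cn.thetad_by_bin(low, bins, emb)

    args.out.mkdir(parents=True, exist_ok=True)
    trend = pf.join(td, lsuffix="_paralog")
    trend.to_csv(args.out / "quartile_trends.tsv", sep="\t")
    print("quartile trends (low-degree subset):")
    for q in ("Q1", "Q2", "Q3", "Q4"):
        print(
            f"  {q}: n={int(pf.loc[q, 'n'])}  paralog fraction {pf.loc[q, 'paralog_fraction']:.3f}"
            f"  median thetad {td.loc[q, 'median']:.3f} rad"
        )

    pos = pd.read_csv(args.labels, sep="\t")[["common", "v1", "v2"]]
    merged = scores.merge(pos.assign(is_pos=True), how="left", on=["common", "v1", "v2"])
    sets = {
        "all_predictions": scores["score"].to_numpy(),
        "cooperative_labels": merged.loc[merged["is_pos"].notna(), "score"].to_numpy(),
        "low_degree_subset": low["score"].to_numpy(),
    }
    summary = cn.score_distribution_summary(sets)
    summary.to_csv(args.out / "score_distributions.tsv", sep="\t")
    for name, row in summary.iterrows():
        print(f"  {name}: n={row['n']}  median score {row['median']:.3f}")
    print(f"wrote interpretation tables to {args.out}/")


if __name__ == "__main__":
    main()
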