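#!/usr/bin/env python
"""Train the cooperative-vs-competitive classifier and score every triplet.

Builds the 42-feature matrix for the labeled dataset (structural positives
against a sampled unlabeled negative pool), applies the 50% V1/V2 order
randomization, runs the 70/30 split + undersampling + repeated
cross-validation protocol, fits the Random Forest and the four benchmark
models, and streams scores over the whole open-triangle universe.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import coopnet as cn
from coopnet.embedding import read_coordinates
from coopnet.geometry import PSModelParams
from coopnet.models import CrossValSpec, ModelSpec
from coopnet.network import build_network, largest_connected_component, load_scored_edges
from coopnet.triplets import Triplet


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--edges", type=Path, default=Path("results/synthetic/edges.tsv"))
    ap.add_argument("--coords", type=Path, default=Path("results/embedding/coordinates.tsv"))
    ap.add_argument("--centralities", type=Path, default=Path("results/embedding/centralities.tsv"))
    ap.add_argument("--annotations", type=Path, default=Path("results/synthetic/annotations.tsv"))
    ap.add_argument("--triplets", type=Path, default=Path("results/triplets/open_triangles.tsv"))
    ap.add_argument("--labels", type=Path, default=Path("results/triplets/cooperative_labels.tsv"))
    ap.add_argument("--negative-pool", type=int, default=2000,
                    help="unlabeled open triangles drawn as the noisy negative class")
    ap.add_argument("--cv-repeats", type=int, default=10)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=Path, default=Path("results/model"))
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)

    net = largest_connected_component(
        build_network(load_scored_edges(str(args.edges)), min_score=0.71)
    )
    emb = read_coordinates(args.coords, net, PSModelParams())
    cents = pd.read_csv(args.centralities, sep="\t", index_col="protein")
    ann = pd.read_csv(args.annotations, sep="\t", index_col="protein")

    universe = pd.read_csv(args.triplets, sep="\t")
    pos_keys = pd.read_csv(args.labels, sep="\t")[["common", "v1", "v2"]]
    positives = [Triplet(*row) for row in pos_keys.itertuples(index=False)]
    pos_set = set(positives)
    unlabeled = [
        Triplet(*row)
        for row in universe.itertuples(index=False)
        if Triplet(*row) not in pos_set
    ]
    n_neg = min(args.negative_pool, len(unlabeled))
    negatives = [unlabeled[i] for i in rng.choice(len(unlabeled), size=n_neg, replace=False)]
    print(f"dataset: {len(positives)} cooperative, {n_neg} noisy-negative triplets")

    labels = {t: "cooperative" for t in positives} | {t: "competitive" for t in negatives}
    df = cn.attach_labels(
        cn.build_feature_matrix(positives + negatives, emb, cents, ann), labels
    )
    df = cn.randomize_partner_order(df, seed=args.seed + 1)

    train, test = cn.stratified_split(df, seed=args.seed + 2)
    balanced = cn.undersample_majority(train, seed=args.seed + 3)
    print(f"training: {len(balanced)} balanced rows after undersampling, {len(test)} test rows")

    cv = cn.cross_validate(
        balanced, ModelSpec(), CrossValSpec(5, args.cv_repeats), seed=args.seed + 4
    )
    print(f"cross-validation AUC: {cv['mean']:.3f} +/- {cv['sd']:.3f} over {cv['n_fits']} fits")

    args.out.mkdir(parents=True, exist_ok=True)
    benchmarks = {}
    for algo in ("random_forest", "svm", "logistic_regression", "decision_tree", "knn"):
        model = cn.train_model(balanced, ModelSpec(algo), seed=args.seed + 5)
        rep = cn.evaluate(model, test)
        benchmarks[algo] = {
            "accuracy": round(rep.accuracy, 4),
            "f1": round(rep.f1, 4),
            "sensitivity": round(rep.sensitivity, 4),
            "specificity": round(rep.specificity, 4),
            "auc": round(rep.auc, 4),
        }
        print(f"{algo:20s} acc {rep.accuracy:.3f}  F1 {rep.f1:.3f}  AUC {rep.auc:.3f}")

    rf = cn.train_model(balanced, ModelSpec(), seed=args.seed + 5)
    imp = cn.permutation_importance(rf, test, n_permutations=10, seed=args.seed + 6)
    imp.to_csv(args.out / "importance.tsv", sep="\t", index=False)
    print(f"top features: {', '.join(imp['feature'].head(5))}")

    features_all = cn.build_feature_matrix(
        [Triplet(*row) for row in universe.itertuples(index=False)], emb, cents, ann
    )
    scores, counts = cn.score_triplets(rf, features_all)
    scores.to_csv(args.out / "scores.tsv", sep="\t", index=False)
    print(f"scored {len(scores)} triplets: {counts[0.5]} with score >= 0.5, {counts[0.9]} >= 0.9")

    rep = cn.evaluate(rf, test)
    with open(args.out / "report.json", "w") as fh:
        json.dump(
            {
                "cv": cv,
                "benchmarks": benchmarks,
                "rf_confusion": rep.confusion,
                "score_counts": {str(k): v for k, v in counts.items()},
                "n_positives": len(positives),
                "n_negative_pool": n_neg,
            },
            fh,
            indent=2,
        )
    pd.DataFrame(rep.roc_points, columns=["fpr", "tpr"]).to_csv(
        args.out / "roc_rf.tsv", sep="\t", index=False
    )
    print(f"wrote model report, importance, ROC and scores to {args.out}/")


if __name__ == "__main__":
    main()
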