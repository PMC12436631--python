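import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from coopnet.features import attach_labels, build_feature_matrix, randomize_partner_order
from coopnet.models import (
    CrossValSpec,
    ModelSpec,
    cross_validate,
    evaluate,
    permutation_importance,
    score_triplets,
    stratified_split,
    train_model,
    undersample_majority,
)
from coopnet.network import compute_centralities
from coopnet.synthetic import plant_signal_dataset


def toy_dataset(n_pos: int, n_neg: int, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    x_pos = rng.normal(1.0, 1.0, n_pos)
    x_neg = rng.normal(-1.0, 1.0, n_neg)
    return pd.DataFrame(
        {
            "f1": np.concatenate([x_pos, x_neg]),
            "f2": rng.normal(size=n_pos + n_neg),
            "label": ["cooperative"] * n_pos + ["competitive"] * n_neg,
        }
    )


@pytest.fixture(scope="module")
def planted(small_ps_embedding):
    emb = small_ps_embedding
    cents = compute_centralities(emb.graph)
    labeled = plant_signal_dataset(emb, 150, 150, seed=21)
    trips = [t for t, _ in labeled]
    df = attach_labels(build_feature_matrix(trips, emb, cents), dict(labeled))
    return randomize_partner_order(df, seed=22)


class TestStratifiedSplit:
    def test_211_positives_put_148_in_training(self):
        data = toy_dataset(211, 1000)
        train, test = stratified_split(data, seed=0)
        assert (train["label"] == "cooperative").sum() == 148
        assert (test["label"] == "cooperative").sum() == 63

    def test_balanced_ten_ten(self):
        train, test = stratified_split(toy_dataset(10, 10), seed=1)
        assert train["label"].value_counts().tolist() == [7, 7]
        assert test["label"].value_counts().tolist() == [3, 3]

    def test_deterministic_and_exhaustive(self):
        data = toy_dataset(30, 70)
        t1, s1 = stratified_split(data, seed=5)
        t2, s2 = stratified_split(data, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        assert len(t1) + len(s1) == len(data)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(toy_dataset(1, 50))


class TestUndersample:
    def test_148_positives_5000_negatives_give_296(self):
        data = toy_dataset(148, 5000)
        out = undersample_majority(data, seed=0)
        assert len(out) == 296
        assert out["label"].value_counts().tolist() == [148, 148]

    def test_balanced_input_unchanged(self):
        data = toy_dataset(20, 20)
        assert len(undersample_majority(data, seed=0)) == 40

    def test_three_pos_seven_neg_give_six(self):
        out = undersample_majority(toy_dataset(3, 7), seed=0)
        assert len(out) == 6
        assert out["label"].value_counts().tolist() == [3, 3]


class TestCrossValidate:
    def test_fifty_fits_reported(self):
        data = toy_dataset(40, 40)
        res = cross_validate(data, ModelSpec("decision_tree"), CrossValSpec(5, 10), seed=0)
        assert res["n_fits"] == 50

    def test_separable_data_scores_high(self):
        rng = np.random.default_rng(3)
        data = toy_dataset(40, 40)
        data["f1"] = np.where(data["label"] == "cooperative", 5.0, -5.0) + rng.normal(
            0, 0.1, 80
        )
        res = cross_validate(data, ModelSpec("random_forest", n_trees=50), CrossValSpec(5, 2), seed=0)
        assert res["mean"] >= 0.95

    def test_label_permuted_null_is_chance(self):
        rng = np.random.default_rng(4)
        data = toy_dataset(60, 60)
        data["label"] = rng.permutation(data["label"].to_numpy())
        res = cross_validate(
            data, ModelSpec("random_forest", n_trees=50), CrossValSpec(5, 2), seed=0
        )
        assert 0.35 <= res["mean"] <= 0.65

    def test_excess_folds_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(toy_dataset(3, 50), ModelSpec("decision_tree"), CrossValSpec(5, 1))


class TestTrainModel:
    def test_all_five_algorithms_fit_and_score(self, planted):
        for algo in ("random_forest", "svm", "logistic_regression", "decision_tree", "knn"):
            spec = ModelSpec(algo, n_trees=50)
            model = train_model(planted, spec, seed=0)
            scores = model.predict_proba_positive(planted)
            assert scores.shape == (len(planted),)
            assert ((scores >= 0) & (scores <= 1)).all()

    def test_vars_per_split_clamped_with_warning(self):
        data = toy_dataset(20, 20)
        with pytest.warns(UserWarning, match="clamp"):
            model = train_model(data, ModelSpec(n_trees=10, vars_per_split=22), seed=0)
        assert model.estimator.max_features == 2

    def test_rf_separates_planted_signal(self, planted):
        model = train_model(planted, ModelSpec(n_trees=100), seed=1)
        scores = model.predict_proba_positive(planted)
        pos = planted["label"] == "cooperative"
        assert scores[pos.to_numpy()].mean() > scores[(~pos).to_numpy()].mean()


class TestEvaluate:
    def test_hand_computed_confusion(self):
        # scores arranged to give TP=8 FP=2 FN=2 TN=8 at threshold 0.5
        df = pd.DataFrame(
            {
                "f1": np.zeros(20),
                "label": ["cooperative"] * 10 + ["competitive"] * 10,
            }
        )
        scores = np.array([0.9] * 8 + [0.1] * 2 + [0.9] * 2 + [0.1] * 8)

        class Frozen:
            feature_columns = ["f1"]
            spec = None

            def predict_proba_positive(self, x):
                return scores[: len(x)]

        rep = evaluate(Frozen(), df)
        assert rep.confusion == (8, 2, 2, 8)
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(0.8)

    def test_auc_matches_rank_statistic_oracle(self, planted):
        model = train_model(planted, ModelSpec(n_trees=60), seed=2)
        train, test = stratified_split(planted, seed=3)
        rep = evaluate(model, test)
        scores = model.predict_proba_positive(test)
        pos = (test["label"] == "cooperative").to_numpy()
        u = mannwhitneyu(scores[pos], scores[~pos]).statistic
        assert rep.auc == pytest.approx(u / (pos.sum() * (~pos).sum()), abs=1e-9)

    def test_perfect_and_degenerate_scores(self):
        df = pd.DataFrame({"f1": np.zeros(10), "label": ["cooperative"] * 5 + ["competitive"] * 5})

        class Const:
            feature_columns = ["f1"]
            spec = None

            def __init__(self, scores):
                self._s = np.asarray(scores)

            def predict_proba_positive(self, x):
                return self._s

        perfect = evaluate(Const([0.9] * 5 + [0.1] * 5), df)
        assert perfect.auc == pytest.approx(1.0)
        flat = evaluate(Const([0.5] * 10), df)
        assert flat.auc == pytest.approx(0.5)

    def test_single_class_test_set_rejected(self, planted):
        model = train_model(planted, ModelSpec("decision_tree"), seed=0)
        pos_only = planted[planted["label"] == "cooperative"]
        with pytest.raises(ValueError):
            evaluate(model, pos_only)

    def test_metrics_consistent_with_confusion(self, planted):
        model = train_model(planted, ModelSpec(n_trees=60), seed=4)
        _, test = stratified_split(planted, seed=5)
        rep = evaluate(model, test)
        tp, fp, fn, tn = rep.confusion
        assert rep.accuracy == pytest.approx((tp + tn) / (tp + fp + fn + tn))
        assert rep.sensitivity == pytest.approx(tp / (tp + fn))
        assert rep.specificity == pytest.approx(tn / (tn + fp))


class TestPermutationImportance:
    def test_planted_feature_ranks_first(self, planted):
        model = train_model(planted, ModelSpec(n_trees=100), seed=6)
        imp = permutation_importance(model, planted, n_permutations=5, seed=7)
        assert imp.iloc[0]["feature"] == "v1v2_thetad"
        assert list(imp["rank"]) == list(range(1, 43))

    def test_constant_column_importance_exactly_zero(self, planted):
        data = planted.copy()
        data["common_idr"] = 0.0
        model = train_model(data, ModelSpec(n_trees=50), seed=8)
        imp = permutation_importance(model, data, n_permutations=3, seed=9)
        row = imp[imp["feature"] == "common_idr"]
        assert float(row["mean_decrease_accuracy"].iloc[0]) == 0.0

    def test_noise_feature_importance_near_zero(self):
        # importance must be read on held-out rows: on the training rows a
        # forest memorises even pure noise
        data = toy_dataset(500, 500, seed=10)
        train, test = stratified_split(data, seed=10)
        model = train_model(train, ModelSpec(n_trees=80), seed=10)
        imp = permutation_importance(model, test, n_permutations=10, seed=11)
        noise = float(imp.loc[imp["feature"] == "f2", "mean_decrease_accuracy"].iloc[0])
        assert abs(noise) < 0.05


class TestScoreTriplets:
    def test_streaming_counts_partition_rows(self, planted):
        model = train_model(planted, ModelSpec(n_trees=50), seed=12)
        table, counts = score_triplets(model, planted, thresholds=(0.5,), chunk_size=64)
        below = int((table["score"] < 0.5).sum())
        assert counts[0.5] + below == len(planted)
        assert list(table.columns[:3]) == ["common", "v1", "v2"]

    def test_separable_fixture_orders_classes(self, planted):
        model = train_model(planted, ModelSpec(n_trees=50), seed=13)
        table, _ = score_triplets(model, planted)
        pos = (planted["label"] == "cooperative").to_numpy()
        assert table["score"][pos].mean() > table["score"][~pos].mean()

    def test_empty_stream(self, planted):
        model = train_model(planted, ModelSpec(n_trees=10), seed=14)
        table, counts = score_triplets(model, iter([]), thresholds=(0.5, 0.9))
        assert len(table) == 0
        assert counts == {0.5: 0, 0.9: 0}

    def test_schema_mismatch_reported(self, planted):
        model = train_model(planted, ModelSpec(n_trees=10), seed=15)
        with pytest.raises(ValueError, match="missing"):
            score_triplets(model, planted.drop(columns=["v1v2_thetad"]))
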