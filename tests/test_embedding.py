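import math

import networkx as nx
import numpy as np
import pytest

from coopnet.embedding import (
    EmbedConfig,
    angular_recovery,
    circular_correlation,
    embedding_log_likelihood,
    estimate_gamma,
    hypermap_refine,
    labne_embed,
    radius_by_rank,
    read_coordinates,
    write_coordinates,
)
from coopnet.geometry import PSModelParams
from coopnet.synthetic import ps_generate


class TestLabne:
    def test_star_center_is_innermost(self, ps_params_study):
        g = nx.star_graph(4)
        g = nx.relabel_nodes(g, {v: f"P{v}" for v in g.nodes()})
        emb = labne_embed(g, ps_params_study)
        center = emb.coords.loc["P0", "r"]
        assert all(center < emb.coords.loc[f"P{i}", "r"] for i in range(1, 5))

    def test_rank_one_radius_formula(self):
        beta = 1.0 / (2.97 - 1.0)
        r1 = radius_by_rank(np.array([1]), 100, beta)[0]
        assert r1 == pytest.approx(2 * (1 - beta) * math.log(100))
        assert r1 == pytest.approx(4.533, abs=0.01)

    def test_radii_nondecreasing_in_degree_rank(self, small_ps_embedding, ps_params_study):
        emb = labne_embed(small_ps_embedding.graph, ps_params_study)
        order = sorted(
            emb.graph.nodes(), key=lambda v: (-emb.graph.degree(v), v)
        )
        radii = emb.coords.loc[order, "r"].to_numpy()
        assert np.all(np.diff(radii) >= -1e-12)

    def test_disconnected_input_rejected(self, ps_params_study):
        g = nx.Graph([("A", "B"), ("C", "D")])
        with pytest.raises(ValueError):
            labne_embed(g, ps_params_study)

    def test_deterministic_across_runs(self, small_ps_embedding, ps_params_study):
        a = labne_embed(small_ps_embedding.graph, ps_params_study)
        b = labne_embed(small_ps_embedding.graph, ps_params_study)
        assert np.allclose(a.coords.to_numpy(), b.coords.to_numpy())


class TestHypermapRefine:
    def test_single_candidate_keeps_coordinates(self, small_ps_embedding, ps_params_study):
        emb = labne_embed(small_ps_embedding.graph, ps_params_study)
        cfg = EmbedConfig(n_candidates=1)
        out = hypermap_refine(emb, cfg)
        assert np.allclose(out.coords.to_numpy(), emb.coords.to_numpy())

    def test_log_likelihood_never_decreases(self, ps_params_cold):
        truth = ps_generate(ps_params_cold, 150, seed=3)
        emb = labne_embed(truth.graph, ps_params_cold)
        refined = hypermap_refine(emb, EmbedConfig(seed=3))
        assert embedding_log_likelihood(refined) >= embedding_log_likelihood(emb) - 1e-9

    def test_radii_unchanged(self, ps_params_cold):
        truth = ps_generate(ps_params_cold, 120, seed=4)
        emb = labne_embed(truth.graph, ps_params_cold)
        refined = hypermap_refine(emb, EmbedConfig(seed=4))
        assert np.allclose(refined.coords["r"], emb.coords["r"])

    def test_mean_recovery_not_degraded(self, ps_params_cold):
        """Refinement does not lose ground-truth angular signal on average."""
        before, after = [], []
        for seed in range(1, 6):
            truth = ps_generate(ps_params_cold, 200, seed=seed)
            emb = labne_embed(truth.graph, ps_params_cold)
            refined = hypermap_refine(emb, EmbedConfig(seed=seed))
            before.append(angular_recovery(truth, emb))
            after.append(angular_recovery(truth, refined))
        assert np.mean(after) >= np.mean(before) - 1e-6


class TestRecoveryScaling:
    def test_recovery_improves_or_holds_with_size(self, ps_params_cold):
        means = []
        for n in (100, 300):
            recs = []
            for seed in range(1, 4):
                truth = ps_generate(ps_params_cold, n, seed=seed)
                emb = hypermap_refine(
                    labne_embed(truth.graph, ps_params_cold), EmbedConfig(seed=seed)
                )
                recs.append(angular_recovery(truth, emb))
            means.append(np.mean(recs))
        assert means[1] >= means[0] - 0.05
        assert means[1] >= 0.5


class TestEstimateGamma:
    def test_recovers_pure_power_law_exponent(self):
        # integer degrees from a Pareto(4.5, gamma=2.5) law, rounded to the
        # nearest integer (the MLE's -0.5 offset undoes that discretisation)
        rng = np.random.default_rng(0)
        x = 4.5 * (1 - rng.random(100_000)) ** (-1 / 1.5)
        degrees = np.round(x).astype(int)

        class DegreeView:
            def degree(self):
                return [(i, int(d)) for i, d in enumerate(degrees)]

        gamma_hat = estimate_gamma(DegreeView(), k_min=5)
        assert 2.4 <= gamma_hat <= 2.6

    def test_recovers_generator_exponent_on_ps_network(self, ps_params_study):
        emb = ps_generate(PSModelParams(m=3), 3000, seed=9)
        gamma_hat = estimate_gamma(emb.graph)
        assert 2.6 <= gamma_hat <= 3.3

    def test_too_few_qualifying_nodes_rejected(self):
        g = nx.path_graph(8)
        with pytest.raises(ValueError):
            estimate_gamma(g, k_min=5)

    def test_degenerate_constant_tail_warns(self):
        g = nx.Graph()
        # 12 disjoint stars -> hubs all have degree exactly 5... connect them in a cycle
        for i in range(12):
            for j in range(5):
                g.add_edge(f"hub{i}", f"leaf{i}_{j}")
        with pytest.warns(UserWarning, match="degenerate"):
            estimate_gamma(g, k_min=5)


class TestCircularCorrelation:
    def test_rotation_invariant_and_reflection_flips_sign(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 2 * np.pi, 200)
        assert circular_correlation(a, (a + 1.3) % (2 * np.pi)) == pytest.approx(1.0)
        assert circular_correlation(a, (-a) % (2 * np.pi)) == pytest.approx(-1.0)

    def test_independent_angles_near_zero(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(0, 2 * np.pi, (2, 2000))
        assert abs(circular_correlation(a, b)) < 0.1


def test_coordinate_tsv_round_trip(tmp_path, ps_params_cold):
    emb = ps_generate(ps_params_cold, 50, seed=5)
    path = tmp_path / "coords.tsv"
    write_coordinates(emb, path)
    back = read_coordinates(path, emb.graph, ps_params_cold)
    assert np.allclose(
        back.coords.sort_index().to_numpy(), emb.coords.sort_index().to_numpy(), atol=1e-9
    )
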