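import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from miltext.classifier import CascadeResult
from miltext.network import (
    SUBGROUPS,
    ComparisonResult,
    FactorMatrix,
    GaussianGraphicalModel,
    Partition,
    compare_networks,
    density,
    estimate_network,
    expected_influence,
    louvain,
    modularity,
    split_subgroups,
)
from miltext import synthgen as syn


def brute_force_max_modularity(G):
    """Exhaustive search over all set partitions (<= 8 nodes)."""
    nodes = list(G.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for p in partitions(rest):
            for i in range(len(p)):
                yield p[:i] + [[first] + p[i]] + p[i + 1:]
            yield [[first]] + p

    return max(modularity(G, [set(b) for b in p]) for p in partitions(nodes))


class TestSplitSubgroups:
    def _result(self, pid, sfm, pom):
        return CascadeResult(pid, "RELATED", 0.9, sfm=sfm, sfm_prob=0.8,
                             pom=pom, pom_prob=0.8)

    def test_post_membership(self):
        res = [self._result("p0", "HIGH", "LOW")]
        mats = split_subgroups(res, {"p0": {"a": 2}}, columns=["a", "b"])
        for g in ("S1", "P0", "S1P0"):
            assert list(mats[g].data.index) == ["p0"]
            assert mats[g].data.loc["p0", "a"] == 2
        for g in ("S0", "P1", "S1P1", "S0P1", "S0P0"):
            assert mats[g].n == 0

    def test_one_post_per_quadrant(self):
        res = [self._result("p0", "HIGH", "HIGH"), self._result("p1", "HIGH", "LOW"),
               self._result("p2", "LOW", "HIGH"), self._result("p3", "LOW", "LOW")]
        mats = split_subgroups(res, {r.post_id: {} for r in res}, columns=["a"])
        assert all(mats[g].n == 2 for g in ("S1", "S0", "P1", "P0"))
        assert all(mats[g].n == 1 for g in ("S1P1", "S1P0", "S0P1", "S0P0"))

    def test_empty_input(self):
        mats = split_subgroups([], {}, columns=["a"])
        assert set(mats) == set(SUBGROUPS)
        assert all(m.n == 0 for m in mats.values())

    def test_unrelated_posts_skipped(self):
        res = [CascadeResult("p0", "NOT_RELATED", 0.1)]
        mats = split_subgroups(res, {}, columns=["a"])
        assert all(m.n == 0 for m in mats.values())

    def test_missing_level_label_errors(self):
        bad = CascadeResult("p0", "RELATED", 0.9)
        with pytest.raises(ValueError, match="p0"):
            split_subgroups([bad], {}, columns=["a"])


class TestEstimateNetwork:
    def test_independent_columns_give_empty_graph(self):
        X, edges, _ = syn.gen_gaussian(syn.make_precision(5, "empty"), n=500, seed=2)
        res = estimate_network(X)
        assert res.n_edges == 0 and edges == set()

    def test_chain_recovered_exactly(self):
        X, edges, _ = syn.gen_gaussian(syn.make_precision(5, "chain", -0.4),
                                       n=2000, seed=7)
        res = estimate_network(X)
        iu = np.triu_indices(5, 1)
        est = {(i, j) for i, j in zip(*iu) if abs(res.weights[i, j]) > 1e-10}
        assert est == edges

    def test_gamma_zero_reduces_to_bic(self):
        X, _, _ = syn.gen_gaussian(syn.make_precision(4, "chain", -0.3),
                                   n=400, seed=3)
        path0 = estimate_network(X, gamma=0.0).ebic_path.set_index("alpha")
        path5 = estimate_network(X, gamma=0.5).ebic_path.set_index("alpha")
        # EBIC(gamma) = BIC + 4 E gamma log p on every shared grid point
        joined = path0.join(path5, lsuffix="_0", rsuffix="_5", how="inner")
        expected = joined.ebic_0 + 4 * joined.n_edges_0 * 0.5 * np.log(4)
        assert np.allclose(joined.ebic_5, expected)

    def test_selected_ebic_is_grid_minimum(self):
        X, _, _ = syn.gen_gaussian(syn.make_precision(6, "chain", -0.35),
                                   n=800, seed=4)
        res = estimate_network(X)
        assert res.ebic == pytest.approx(res.ebic_path.ebic.min())

    def test_weights_are_symmetric_partial_correlations(self):
        X, _, _ = syn.gen_gaussian(syn.make_precision(5, "chain", -0.4),
                                   n=1000, seed=5)
        res = estimate_network(X)
        assert np.allclose(res.weights, res.weights.T)
        assert np.allclose(np.diag(res.weights), 0)
        assert np.all(np.abs(res.weights) <= 1)

    def test_row_permutation_invariant(self):
        X, _, _ = syn.gen_gaussian(syn.make_precision(5, "chain", -0.4),
                                   n=600, seed=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(X))
        res_a = estimate_network(X)
        res_b = estimate_network(X.iloc[perm])
        assert np.allclose(res_a.weights, res_b.weights, atol=1e-6)

    def test_zero_variance_column_dropped(self):
        X, _, _ = syn.gen_gaussian(syn.make_precision(4, "chain", -0.3),
                                   n=300, seed=8)
        X["const"] = 1.0
        res = estimate_network(X)
        assert res.dropped_columns == ["const"]
        assert res.p == 4

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            GaussianGraphicalModel(pd.DataFrame(np.zeros((2, 3))))

    def test_summary_mentions_key_quantities(self):
        X, _, _ = syn.gen_gaussian(syn.make_precision(4, "chain", -0.3),
                                   n=400, seed=9)
        s = GaussianGraphicalModel(X, subgroup="S1P0").fit().summary()
        assert "S1P0" in s and "density" in s and "expected influence" in s


class TestExpectedInfluence:
    def test_signed_sum(self):
        W = np.array([[0.0, 0.3, -0.1], [0.3, 0.0, 0.0], [-0.1, 0.0, 0.0]])
        ei = expected_influence(W, ["a", "b", "c"])
        assert ei.loc["a", "expected_influence_raw"] == pytest.approx(0.2)

    def test_empty_network_all_zero(self):
        ei = expected_influence(np.zeros((4, 4)))
        assert (ei.expected_influence_raw == 0).all()
        assert (ei.expected_influence_z == 0).all()

    def test_equals_row_sums_on_random_matrices(self, rng):
        for _ in range(100):
            p = int(rng.integers(3, 12))
            A = rng.normal(size=(p, p))
            W = (A + A.T) / 2
            np.fill_diagonal(W, 0.0)
            ei = expected_influence(W)
            assert np.allclose(ei.expected_influence_raw.to_numpy(), W.sum(axis=1))

    def test_z_scores_standardized(self, rng):
        A = rng.normal(size=(6, 6))
        W = (A + A.T) / 2
        np.fill_diagonal(W, 0.0)
        z = expected_influence(W).expected_influence_z
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0)


class TestDensityModularity:
    @pytest.mark.parametrize("n,e,expected", [(5, 10, 1.0), (4, 3, 0.5), (6, 0, 0.0)])
    def test_density_formula(self, n, e, expected):
        assert density(n, e) == pytest.approx(expected)

    def test_density_needs_two_nodes(self):
        with pytest.raises(ValueError):
            density(1, 0)

    def test_single_community_q_zero(self, rng):
        for _ in range(20):
            G = nx.gnp_random_graph(int(rng.integers(3, 10)), 0.5,
                                    seed=int(rng.integers(2**31)))
            if G.number_of_edges() == 0:
                continue
            assert modularity(G, [set(G.nodes)]) == pytest.approx(0.0)

    def test_two_disconnected_edges_q_half(self):
        G = nx.Graph([("a", "b"), ("c", "d")])
        assert modularity(G, [{"a", "b"}, {"c", "d"}]) == pytest.approx(0.5)

    def test_relabeling_invariant(self):
        G = nx.Graph([("a", "b"), ("c", "d"), ("b", "c")])
        q1 = modularity(G, [{"a", "b"}, {"c", "d"}])
        q2 = modularity(G, [{"c", "d"}, {"a", "b"}])
        assert q1 == pytest.approx(q2)

    def test_uncovered_node_rejected(self):
        G = nx.Graph([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError):
            modularity(G, [{"a", "b"}, {"c"}])


class TestLouvain:
    def test_two_cliques_with_bridge(self):
        G = nx.Graph()
        left, right = range(4), range(4, 8)
        G.add_edges_from(itertools.combinations(left, 2))
        G.add_edges_from(itertools.combinations(right, 2))
        G.add_edge(0, 4)
        part = louvain(G, seed=0)
        assert part.communities in ([set(left), set(right)],
                                    [set(right), set(left)])
        assert part.Q == pytest.approx(brute_force_max_modularity(G))

    def test_single_edge_matches_brute_force(self):
        G = nx.Graph([("a", "b")])
        part = louvain(G, seed=1)
        assert part.Q == pytest.approx(brute_force_max_modularity(G))

    def test_seeded_determinism(self):
        G = nx.gnp_random_graph(10, 0.4, seed=7)
        p1, p2 = louvain(G, seed=5), louvain(G, seed=5)
        assert p1.community_of == p2.community_of and p1.Q == p2.Q

    def test_q_at_least_singleton_partition(self):
        G = nx.gnp_random_graph(12, 0.3, seed=3)
        part = louvain(G, seed=0)
        singletons = [{n} for n in G.nodes]
        assert part.Q >= modularity(G, singletons) - 1e-12

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain(nx.Graph(), seed=0)


class TestCompareNetworks:
    def _two_samples(self, seed, delta_edge=False):
        K = syn.make_precision(4, "chain", -0.3)
        Xa, _, _ = syn.gen_gaussian(K, n=150, seed=seed)
        Kb = K.copy()
        if delta_edge:
            Kb[0, 3] = Kb[3, 0] = -0.45
        Xb, _, _ = syn.gen_gaussian(Kb, n=150, seed=seed + 1000)
        return Xa, Xb

    def test_identical_matrices_zero_diffs(self):
        Xa, _ = self._two_samples(1)
        r = compare_networks(Xa, Xa.copy(), n_perm=20, seed=0)
        assert r.global_strength_diff == pytest.approx(0.0, abs=1e-10)
        assert r.max_weight_diff == pytest.approx(0.0, abs=1e-10)
        assert 0 <= r.p_strength <= 1 and 0 <= r.p_weight <= 1

    def test_planted_edge_detected(self):
        K = syn.make_precision(4, "empty")
        Xa, _, _ = syn.gen_gaussian(K, n=1000, seed=3)
        Kb = K.copy()
        Kb[0, 1] = Kb[1, 0] = -0.5
        Xb, _, _ = syn.gen_gaussian(Kb, n=1000, seed=4)
        r = compare_networks(Xa, Xb, n_perm=99, seed=5)
        assert r.p_weight <= 0.05

    def test_mismatched_columns_rejected(self):
        Xa, Xb = self._two_samples(2)
        Xb = Xb.rename(columns={"x0": "zz"})
        with pytest.raises(ValueError):
            compare_networks(Xa, Xb, n_perm=5, seed=0)

    def test_result_fields_valid(self):
        Xa, Xb = self._two_samples(3)
        r = compare_networks(Xa, Xb, n_perm=19, seed=2)
        assert isinstance(r, ComparisonResult)
        assert r.global_strength_diff >= 0 and r.max_weight_diff >= 0
        assert r.n_perm == 19


class TestResultsObject:
    def test_to_graph_and_communities(self):
        X, _, _ = syn.gen_gaussian(syn.make_precision(6, "block", -0.35),
                                   n=1500, seed=11)
        res = estimate_network(X)
        G = res.to_graph()
        assert G.number_of_nodes() == 6
        part = res.communities(seed=0)
        assert isinstance(part, Partition)
        assert -0.5 <= part.Q <= 1.0
        assert set(part.community_of) == set(res.columns)
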