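"""Community detection and centrality, checked against exhaustive oracles."""

import numpy as np
import pytest

from symptomnet import (
    CentralityProfile,
    UndefinedConsistencyError,
    betweenness_centrality,
    centrality_consistency,
    closeness_centrality,
    degree_centrality,
    generate_cohort,
    hub_frequency,
    modularity_q,
    newman_spectral_communities,
    top_items,
    weight_to_length,
)
from symptomnet.network import apply_threshold, build_network
from symptomnet.preprocess import orient_items, quantile_normalize

from conftest import (
    betweenness_oracle,
    clique_pair,
    closeness_oracle,
    modularity_oracle,
    net_from,
    planted_spec,
    sym,
)


class TestModularityQ:
    def test_single_community_gamma_one_is_zero(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.2, 1, (6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        net = net_from(w)
        assert modularity_q(net, np.zeros(6, int), gamma=1.0) == pytest.approx(0.0)

    def test_two_cliques_component_partition(self, two_cliques):
        q = modularity_q(two_cliques, [0] * 4 + [1] * 4, gamma=1.0)
        assert q == pytest.approx(0.5)
        # cross-check against the exhaustive double-sum formula
        oracle = modularity_oracle(two_cliques.weights, [0] * 4 + [1] * 4, 1.0)
        assert q == pytest.approx(oracle)

    def test_delta_q_of_cutting_one_edge(self):
        """Separating one edge's endpoints removes exactly that edge's
        positive term; dQ matches the direct bookkeeping oracle."""
        w = sym(4, {(0, 1): 0.5, (1, 2): 0.4, (2, 3): 0.6, (0, 3): 0.3})
        net = net_from(w)
        base = np.zeros(4, int)
        split = np.array([0, 1, 1, 1])  # cuts edges (0,1) and (0,3)
        gamma = 0.7
        dq = modularity_q(net, split, gamma) - modularity_q(net, base, gamma)
        assert dq == pytest.approx(
            modularity_oracle(w, split, gamma) - modularity_oracle(w, base, gamma)
        )

    def test_incomplete_assignment_rejected(self, two_cliques):
        with pytest.raises(ValueError):
            modularity_q(two_cliques, [0, 1], gamma=1.0)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            modularity_q(net_from(np.zeros((3, 3))), [0, 0, 0], gamma=1.0)


class TestSpectralCommunities:
    def test_bridged_cliques_recovered_and_globally_optimal(self, bridged_cliques):
        from conftest import max_modularity_exhaustive

        part = newman_spectral_communities(bridged_cliques, gamma=0.4)
        assert part.n_communities == 2
        assert set(map(tuple, [np.where(part.assignment == c)[0]
                               for c in range(2)])) == {
            (0, 1, 2, 3), (4, 5, 6, 7)}
        best = max_modularity_exhaustive(bridged_cliques.weights, 0.4)
        assert part.q_score == pytest.approx(best, abs=1e-12)

    def test_singleton_network(self):
        net = net_from(np.zeros((1, 1)))
        part = newman_spectral_communities(net)
        assert part.assignment.tolist() == [0]
        assert part.q_score == 0.0

    def test_edgeless_network_single_community(self):
        part = newman_spectral_communities(net_from(np.zeros((4, 4))))
        assert part.n_communities == 1
        assert part.q_score == 0.0

    def test_q_score_consistent_with_modularity_q(self, bridged_cliques):
        part = newman_spectral_communities(bridged_cliques, gamma=0.4)
        assert part.q_score == pytest.approx(
            modularity_q(bridged_cliques, part.assignment, gamma=0.4)
        )

    def test_never_below_trivial_partition(self):
        rng = np.random.default_rng(1)
        for seed in range(4):
            rng = np.random.default_rng(seed)
            w = rng.uniform(0, 1, (7, 7)) * (rng.random((7, 7)) < 0.5)
            w = np.triu(w, 1)
            w = w + w.T
            if not w.any():
                continue
            net = net_from(w)
            part = newman_spectral_communities(net, gamma=0.4)
            trivial = modularity_q(net, np.zeros(7, int), gamma=0.4)
            assert part.q_score >= trivial - 1e-12

    def test_planted_three_modules_recovered(self):
        """Light planted-partition check (5 seeds; 20-seed sweep is an
        acceptance criterion)."""
        from sklearn.metrics import adjusted_rand_score

        hits = 0
        for seed in range(5):
            spec, truth = planted_spec(n_subjects=1000, seed=seed)
            ds = generate_cohort(spec)
            clean = orient_items(quantile_normalize(ds))
            net = build_network(clean, threshold=0.2)
            part = newman_spectral_communities(net, gamma=0.4)
            if adjusted_rand_score(truth, part.assignment) >= 0.9:
                hits += 1
        assert hits >= 4

    def test_ids_contiguous_from_zero(self, bridged_cliques):
        part = newman_spectral_communities(bridged_cliques, gamma=1.0)
        ids = np.unique(part.assignment)
        np.testing.assert_array_equal(ids, np.arange(len(ids)))

    def test_deterministic_across_calls(self, bridged_cliques):
        a = newman_spectral_communities(bridged_cliques, gamma=0.4, seed=1)
        b = newman_spectral_communities(bridged_cliques, gamma=0.4, seed=99)
        np.testing.assert_array_equal(a.assignment, b.assignment)


class TestWeightToLength:
    def test_reciprocal_values(self):
        net = net_from(sym(3, {(0, 1): 0.5, (1, 2): 1.0}))
        lengths = weight_to_length(net)
        assert lengths[0, 1] == pytest.approx(2.0)
        assert lengths[1, 2] == pytest.approx(1.0)
        assert np.isinf(lengths[0, 2])

    def test_stronger_edge_never_longer(self):
        rng = np.random.default_rng(2)
        w = rng.uniform(0.1, 1, (5, 5))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        lengths = weight_to_length(net_from(w))
        iu = np.triu_indices(5, 1)
        order_w = np.argsort(w[iu])
        assert np.all(np.diff(lengths[iu][order_w]) <= 1e-12)


class TestBetweenness:
    def test_three_node_path(self):
        net = net_from(sym(3, {(0, 1): 1.0, (1, 2): 1.0}))
        np.testing.assert_allclose(betweenness_centrality(net), [0, 1, 0])

    def test_four_node_star(self):
        net = net_from(sym(4, {(0, 1): 1.0, (0, 2): 1.0, (0, 3): 1.0}))
        np.testing.assert_allclose(betweenness_centrality(net), [3, 0, 0, 0])

    def test_random_network_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(0.2, 1, (7, 7)) * (rng.random((7, 7)) < 0.6)
        w = np.triu(w, 1)
        w = w + w.T
        net = net_from(w)
        np.testing.assert_allclose(
            betweenness_centrality(net), betweenness_oracle(w), atol=1e-9
        )

    def test_unweighted_equivalent_reduces_to_textbook(self):
        """All-equal weights: same result as binary-graph betweenness."""
        import networkx as nx

        w = sym(6, {(0, 1): 0.5, (1, 2): 0.5, (2, 3): 0.5, (3, 4): 0.5,
                    (1, 4): 0.5, (4, 5): 0.5})
        net = net_from(w)
        G = nx.from_numpy_array((w > 0).astype(int))
        expected = nx.betweenness_centrality(G, normalized=False)
        np.testing.assert_allclose(
            betweenness_centrality(net),
            [expected[i] for i in range(6)], atol=1e-9,
        )


class TestDegree:
    def test_complete_graph(self):
        w = sym(5, {(i, j): 0.5 for i in range(5) for j in range(i + 1, 5)})
        np.testing.assert_array_equal(degree_centrality(net_from(w)), [4] * 5)

    def test_isolated_node_zero(self):
        w = sym(3, {(0, 1): 0.5})
        np.testing.assert_array_equal(degree_centrality(net_from(w)), [1, 1, 0])

    def test_handshake_identity(self):
        rng = np.random.default_rng(4)
        w = rng.uniform(0.2, 1, (8, 8)) * (rng.random((8, 8)) < 0.4)
        w = np.triu(w, 1)
        w = w + w.T
        net = net_from(w)
        assert degree_centrality(net).sum() == 2 * net.edge_count

    def test_weighted_strength_option(self):
        w = sym(3, {(0, 1): 0.5, (0, 2): 0.3})
        np.testing.assert_allclose(
            degree_centrality(net_from(w), weighted=True), [0.8, 0.5, 0.3]
        )


class TestCloseness:
    def test_unit_path(self):
        net = net_from(sym(3, {(0, 1): 1.0, (1, 2): 1.0}))
        np.testing.assert_allclose(
            closeness_centrality(net), [2 / 3, 1.0, 2 / 3]
        )

    def test_disconnected_node_zero(self):
        net = net_from(sym(3, {(0, 1): 1.0}))
        assert closeness_centrality(net)[2] == 0.0

    def test_two_triangles_match_dijkstra_oracle(self):
        """Disjoint components use the Wasserman-Faust correction; every
        triangle node reaches 2 others at total distance 2, giving
        (2/5)*(2/2) = 0.4."""
        w = sym(6, {(0, 1): 1, (0, 2): 1, (1, 2): 1,
                    (3, 4): 1, (3, 5): 1, (4, 5): 1})
        net = net_from(w)
        values = closeness_centrality(net)
        np.testing.assert_allclose(values, 0.4)
        np.testing.assert_allclose(values, closeness_oracle(w), atol=1e-12)

    def test_random_network_matches_oracle(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0.2, 1, (7, 7)) * (rng.random((7, 7)) < 0.5)
        w = np.triu(w, 1)
        w = w + w.T
        net = net_from(w)
        np.testing.assert_allclose(
            closeness_centrality(net), closeness_oracle(w), atol=1e-9
        )


class TestCentralityInvariance:
    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        w = rng.uniform(0.2, 1, (7, 7)) * (rng.random((7, 7)) < 0.6)
        w = np.triu(w, 1)
        w = w + w.T
        net = net_from(w)
        perm = rng.permutation(7)
        net_p = net_from(w[np.ix_(perm, perm)])
        for fn in (betweenness_centrality, closeness_centrality):
            np.testing.assert_allclose(fn(net_p), fn(net)[perm], atol=1e-9)
        np.testing.assert_array_equal(
            degree_centrality(net_p), degree_centrality(net)[perm]
        )


def _profile(labels, b=None, d=None, c=None):
    m = len(labels)
    z = np.zeros(m)
    return CentralityProfile(
        betweenness=np.asarray(b if b is not None else z, dtype=float),
        degree=np.asarray(d if d is not None else z),
        closeness=np.asarray(c if c is not None else z, dtype=float),
        item_labels=list(labels),
    )


class TestTopItemsAndHubs:
    def test_pure_tie_break_is_alphabetical(self):
        p = _profile(["zeta", "alpha", "mid"], b=[1.0, 1.0, 1.0])
        assert top_items(p, "betweenness", 2) == ["alpha", "mid"]

    def test_sorted_input_order(self):
        p = _profile(["a", "b", "c"], b=[3.0, 2.0, 1.0])
        assert top_items(p, "betweenness", 2) == ["a", "b"]

    def test_two_way_tie_at_rank_three(self):
        p = _profile(["a", "b", "d", "c"], b=[5.0, 4.0, 3.0, 3.0])
        assert top_items(p, "betweenness", 3) == ["a", "b", "c"]

    def test_k_too_large_rejected(self):
        p = _profile(["a"], b=[1.0])
        with pytest.raises(ValueError):
            top_items(p, "betweenness", 2)

    def test_single_profile_counts(self):
        p = _profile(["a", "b", "c", "d"], d=[4, 3, 2, 1])
        counts = hub_frequency([p], "degree", k=3)
        assert counts == {"a": 1, "b": 1, "c": 1, "d": 0}

    def test_unanimous_hub_counts_all_profiles(self):
        profiles = [
            _profile(["hub", f"x{i}", f"y{i}"], c=[9.0, float(i), 0.5])
            for i in range(5)
        ]
        counts = hub_frequency(profiles, "closeness", k=2)
        assert counts["hub"] == 5

    def test_tally_matches_manual_count(self):
        p1 = _profile(["a", "b", "c"], b=[3, 2, 1])
        p2 = _profile(["b", "c", "d"], b=[1, 5, 2])
        p3 = _profile(["a", "d"], b=[1, 2])
        counts = hub_frequency([p1, p2, p3], "betweenness", k=2)
        # manual tally: p1 top2 = a,b; p2 top2 = c,d; p3 top2 = d,a
        assert counts == {"a": 2, "b": 1, "c": 1, "d": 2}


class TestConsistency:
    def test_identical_profiles_r_one(self):
        p = _profile(["a", "b", "c", "d"], b=[1.0, 2.0, 3.0, 4.0])
        assert centrality_consistency(p, p, "betweenness") == pytest.approx(1.0)

    def test_negated_profile_r_minus_one(self):
        p = _profile(["a", "b", "c"], b=[1.0, 2.0, 3.0])
        q = _profile(["a", "b", "c"], b=[-1.0, -2.0, -3.0])
        assert centrality_consistency(p, q, "betweenness") == pytest.approx(-1.0)

    def test_six_item_vectors_match_textbook_pearson(self):
        a = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 7.0])
        b = np.array([2.0, 3.0, 1.0, 9.0, 4.0, 8.0])
        p = _profile(list("abcdef"), c=a)
        q = _profile(list("abcdef"), c=b)
        am, bm = a - a.mean(), b - b.mean()
        expected = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
        assert centrality_consistency(p, q, "closeness") == pytest.approx(expected)

    def test_shared_subset_used(self):
        p = _profile(["a", "b", "c", "x"], d=[1, 2, 3, 99])
        q = _profile(["a", "b", "c", "y"], d=[2, 4, 6, -1])
        assert centrality_consistency(p, q, "degree") == pytest.approx(1.0)

    def test_too_few_shared_items_flagged(self):
        p = _profile(["a", "b"], b=[1.0, 2.0])
        q = _profile(["a", "z"], b=[1.0, 2.0])
        with pytest.raises(UndefinedConsistencyError):
            centrality_consistency(p, q, "betweenness")

    def test_zero_variance_flagged(self):
        p = _profile(["a", "b", "c"], b=[1.0, 1.0, 1.0])
        q = _profile(["a", "b", "c"], b=[1.0, 2.0, 3.0])
        with pytest.raises(UndefinedConsistencyError):
            centrality_consistency(p, q, "betweenness")
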