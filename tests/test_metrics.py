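"""Graph metrics: closed forms, oracle equivalence, null models."""

from itertools import permutations

import numpy as np
import pytest

import connkit as ck
from connkit.core import ValidationError
from connkit.metrics import nodal_shortest_path_length
from conftest import (binary_matrix, complete_graph, path_graph, ring_lattice,
                      star_graph, weighted_matrix)


def dists(m):
    return ck.shortest_paths(ck.edge_lengths(m), m.weighting)


def brute_force_betweenness(m):
    """Exhaustive oracle: enumerate all simple paths, find the shortest, and
    share credit fractionally among equal-length interior nodes."""
    lengths = ck.edge_lengths(m)
    n = m.n_nodes
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            best, best_paths = np.inf, []
            for r in range(n - 2 + 1):
                for mid in permutations([x for x in range(n)
                                         if x not in (s, t)], r):
                    path = (s, *mid, t)
                    L = sum(lengths[a, b] for a, b in zip(path, path[1:]))
                    if not np.isfinite(L):
                        continue
                    if L < best - 1e-12:
                        best, best_paths = L, [path]
                    elif abs(L - best) <= 1e-12:
                        best_paths.append(path)
            if not np.isfinite(best):
                continue
            for path in best_paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(best_paths)
    norm = (n - 1) * (n - 2) / 2
    return bc / norm if norm > 0 else bc


class TestEdgeLengths:
    def test_reciprocal_and_infinite(self):
        m = weighted_matrix([[0, 0.5, 0], [0.5, 0, 2], [0, 2, 0]])
        L = ck.edge_lengths(m)
        assert L[0, 1] == 2.0 and L[1, 2] == 0.5 and np.isinf(L[0, 2])

    def test_binary_edges_unit_length(self):
        L = ck.edge_lengths(path_graph(3))
        assert L[0, 1] == 1.0

    def test_fl_as_cost_flag(self):
        m = weighted_matrix([[0, 4], [4, 0]], weighting="FL")
        assert ck.edge_lengths(m)[0, 1] == 0.25
        assert ck.edge_lengths(m, fl_as_cost=True)[0, 1] == 4.0


class TestShortestPaths:
    def test_binary_path_graph(self):
        d = dists(path_graph(3))
        assert d.d[0, 2] == 2.0

    def test_weighted_triangle_detour(self):
        m = weighted_matrix([[0, 1, 0.25], [1, 0, 1], [0.25, 1, 0]])
        d = dists(m)
        assert d.d[0, 2] == 2.0  # via middle: 1+1 beats direct 1/0.25 = 4

    def test_disconnected_components_infinite(self):
        m = binary_matrix([[0, 1, 0, 0], [1, 0, 0, 0],
                           [0, 0, 0, 1], [0, 0, 1, 0]])
        d = dists(m)
        assert np.isinf(d.d[0, 2])

    def test_dijkstra_equals_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(3, 13)
            upper = np.triu(rng.random((n, n)) *
                            (rng.random((n, n)) < 0.5), 1)
            w = upper + upper.T
            m = weighted_matrix(w)
            L = ck.edge_lengths(m)
            np.testing.assert_allclose(
                ck.shortest_paths(L).d, ck.floyd_warshall_reference(L),
                rtol=1e-12)

    def test_adding_edge_never_increases_distances(self):
        rng = np.random.default_rng(3)
        n = 8
        upper = np.triu((rng.random((n, n)) < 0.3).astype(float), 1)
        w = upper + upper.T
        d0 = dists(binary_matrix(w)).d
        free = np.argwhere(np.triu(w == 0, 1))
        i, j = free[0]
        w2 = w.copy()
        w2[i, j] = w2[j, i] = 1.0
        d1 = dists(binary_matrix(w2)).d
        finite = np.isfinite(d0)
        assert np.all(d1[finite] <= d0[finite] + 1e-12)


class TestEfficiency:
    def test_complete_k4_efficiency_one(self):
        assert ck.global_efficiency(dists(complete_graph(4))) == 1.0

    def test_path3_global_efficiency(self):
        assert ck.global_efficiency(dists(path_graph(3))) == pytest.approx(5 / 6)

    def test_single_edge_among_three(self):
        m = binary_matrix([[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        assert ck.global_efficiency(dists(m)) == pytest.approx(1 / 3)

    def test_path3_characteristic_path_length(self):
        lp, unreach = ck.characteristic_path_length(dists(path_graph(3)))
        assert lp == pytest.approx(4 / 3)
        assert unreach == 0.0

    def test_complete_graph_path_length_one(self):
        lp, _ = ck.characteristic_path_length(dists(complete_graph(5)))
        assert lp == 1.0

    def test_edgeless_graph_infinite(self):
        m = binary_matrix(np.zeros((3, 3)))
        lp, unreach = ck.characteristic_path_length(dists(m))
        assert np.isinf(lp) and unreach == 1.0

    def test_harmonic_mode_reciprocal_of_efficiency(self):
        d = dists(path_graph(4))
        lp, _ = ck.characteristic_path_length(d, mode="harmonic")
        assert lp == pytest.approx(1 / ck.global_efficiency(d))

    def test_removing_edges_degrades_efficiency_and_lengthens_paths(self):
        full = complete_graph(6)
        sparse_vals = full.values.copy()
        sparse_vals[0, 1] = sparse_vals[1, 0] = 0
        sparse = binary_matrix(sparse_vals)
        assert (ck.global_efficiency(dists(sparse))
                <= ck.global_efficiency(dists(full)))
        lp_full, _ = ck.characteristic_path_length(dists(full))
        lp_sparse, _ = ck.characteristic_path_length(dists(sparse))
        assert lp_sparse >= lp_full

    def test_binary_bounds(self, planted_cohort, backbone_mask):
        m = ck.binarize(ck.apply_mask(
            planted_cohort.subjects[0].matrices["binary"], backbone_mask))
        d = dists(m)
        assert 0 < ck.global_efficiency(d) <= 1
        lp, _ = ck.characteristic_path_length(d)
        assert lp >= 1


class TestNodalMetrics:
    def test_path3_nodal_efficiency(self):
        d = dists(path_graph(3))
        assert ck.nodal_efficiency(d, 1) == 1.0
        assert ck.nodal_efficiency(d, 0) == 0.75

    def test_isolated_node_zero(self):
        m = binary_matrix([[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        assert ck.nodal_efficiency(dists(m), 2) == 0.0

    def test_index_out_of_range(self):
        with pytest.raises(ValidationError):
            ck.nodal_efficiency(dists(path_graph(3)), 7)

    def test_degree_centrality_binary_and_weighted(self):
        assert ck.degree_centrality(path_graph(3), 1) == 2.0
        m = weighted_matrix([[0, 0.2, 0.3], [0.2, 0, 0], [0.3, 0, 0]],
                            weighting="FA")
        assert ck.degree_centrality(m, 0) == pytest.approx(0.5)
        assert ck.degree_centrality(star_graph(4), 2) == 1.0

    def test_betweenness_closed_forms(self):
        bc = ck.betweenness_centrality(path_graph(3))
        np.testing.assert_allclose(bc, [0, 1, 0])
        np.testing.assert_allclose(
            ck.betweenness_centrality(complete_graph(4)), 0)
        bc_star = ck.betweenness_centrality(star_graph(5))
        assert bc_star[0] == 1.0 and np.all(bc_star[1:] == 0)

    def test_betweenness_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(4, 9)
            upper = np.triu((rng.random((n, n)) < 0.45).astype(float), 1)
            w = upper + upper.T
            # random positive weights on half the graphs
            if rng.random() < 0.5:
                w = w * np.round(rng.uniform(0.5, 2.0, (n, n)), 2)
                w = np.triu(w, 1) + np.triu(w, 1).T
            m = weighted_matrix(w)
            np.testing.assert_allclose(ck.betweenness_centrality(m),
                                       brute_force_betweenness(m), atol=1e-9)

    def test_nodal_shortest_path_length_path3(self):
        nlp = nodal_shortest_path_length(dists(path_graph(3)))
        np.testing.assert_allclose(nlp, [1.5, 1.0, 1.5])


class TestClusteringAndLocalEfficiency:
    def test_triangle_full_clustering(self):
        c, cp = ck.clustering_coefficient(complete_graph(3))
        np.testing.assert_allclose(c, 1.0)
        assert cp == 1.0

    def test_path_has_no_clustering(self):
        c, cp = ck.clustering_coefficient(path_graph(3))
        assert np.all(c == 0) and cp == 0

    def test_k4_clustering_one(self):
        _, cp = ck.clustering_coefficient(complete_graph(4))
        assert cp == 1.0

    def test_local_efficiency_k4(self):
        e, mean = ck.local_efficiency(complete_graph(4))
        np.testing.assert_allclose(e, 1.0)

    def test_local_efficiency_star_zero(self):
        e, _ = ck.local_efficiency(star_graph(5))
        np.testing.assert_allclose(e, 0.0)

    def test_pendant_node_zero_local_efficiency(self):
        m = binary_matrix([[0, 1, 1, 0], [1, 0, 1, 0],
                           [1, 1, 0, 1], [0, 0, 1, 0]])
        e, _ = ck.local_efficiency(m)
        assert e[3] == 0.0


class TestNullModels:
    def test_degree_sequence_exactly_preserved(self):
        m = ring_lattice(20, 4)
        deg0 = np.sort((m.values > 0).sum(axis=1))
        for seed in range(100):
            r = ck.rewire_preserving_degree(
                m, ck.NullModelConfig(seed=seed))
            np.testing.assert_array_equal(
                np.sort((r.values > 0).sum(axis=1)), deg0)

    def test_weights_travel_with_edges(self):
        rng = np.random.default_rng(0)
        w = ring_lattice(12, 4).values * 0
        m0 = ring_lattice(12, 4).values
        w = m0 * rng.uniform(1, 5, m0.shape)
        w = np.triu(w, 1) + np.triu(w, 1).T
        m = weighted_matrix(w)
        r = ck.rewire_preserving_degree(m, ck.NullModelConfig(seed=3))
        iu = np.triu_indices(12, 1)
        np.testing.assert_allclose(np.sort(r.values[iu][r.values[iu] > 0]),
                                   np.sort(w[iu][w[iu] > 0]))

    def test_same_seed_identical_rewiring(self):
        m = ring_lattice()
        a = ck.rewire_preserving_degree(m, ck.NullModelConfig(seed=5))
        b = ck.rewire_preserving_degree(m, ck.NullModelConfig(seed=5))
        np.testing.assert_array_equal(a.values, b.values)

    def test_tiny_graph_returned_unchanged(self):
        m = binary_matrix([[0, 1], [1, 0]])
        r = ck.rewire_preserving_degree(m, ck.NullModelConfig(seed=1))
        np.testing.assert_array_equal(r.values, m.values)

    def test_rewiring_destroys_lattice_clustering(self):
        m = ring_lattice(20, 4)
        _, cp0 = ck.clustering_coefficient(m)
        lower = 0
        for seed in range(100):
            r = ck.rewire_preserving_degree(m, ck.NullModelConfig(seed=seed))
            _, cp = ck.clustering_coefficient(r)
            lower += cp < cp0
        assert lower >= 95


class TestSmallWorld:
    def test_ring_lattice_is_small_world(self):
        gamma, lam, sigma = ck.small_world_indices(
            ring_lattice(20, 4), ck.NullModelConfig(n_null=100, seed=1))
        assert gamma > 1 and sigma > 1

    def test_dense_random_graph_near_one(self):
        rng = np.random.default_rng(11)
        n = 20
        upper = np.triu((rng.random((n, n)) < 0.5).astype(float), 1)
        m = binary_matrix(upper + upper.T)
        _, _, sigma = ck.small_world_indices(
            m, ck.NullModelConfig(n_null=100, seed=2))
        assert 0.8 <= sigma <= 1.2

    def test_sigma_is_gamma_over_lambda(self):
        gamma, lam, sigma = ck.small_world_indices(
            ring_lattice(16, 4), ck.NullModelConfig(n_null=10, seed=3))
        assert sigma == pytest.approx(gamma / lam, abs=1e-12)

    def test_self_as_null_gives_unity(self):
        m = ring_lattice(16, 4)
        _, cp = ck.clustering_coefficient(m)
        d = dists(m)
        lp, _ = ck.characteristic_path_length(d)
        assert cp / cp == 1.0 and lp / lp == 1.0


class TestPermutationInvariance:
    def test_metrics_invariant_under_node_relabeling(self):
        rng = np.random.default_rng(9)
        n = 10
        upper = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.4), 1)
        w = upper + upper.T
        m = weighted_matrix(w)
        perm = rng.permutation(n)
        mp = weighted_matrix(w[np.ix_(perm, perm)])
        assert (ck.global_efficiency(dists(m))
                == pytest.approx(ck.global_efficiency(dists(mp)), rel=1e-12))
        np.testing.assert_allclose(ck.nodal_efficiency(dists(m))[perm],
                                   ck.nodal_efficiency(dists(mp)))
        np.testing.assert_allclose(ck.degree_centrality(m)[perm],
                                   ck.degree_centrality(mp))
        np.testing.assert_allclose(ck.betweenness_centrality(m)[perm],
                                   ck.betweenness_centrality(mp), atol=1e-12)


class TestComputeAll:
    def test_hubs_have_top_fn_strength(self, planted_cohort, backbone_mask):
        _, ndf = ck.compute_all(planted_cohort, backbone_mask,
                                weightings=("FN",))
        mean_dc = (ndf.groupby("node")["degree_centrality"]
                   .mean().sort_values(ascending=False))
        assert set(mean_dc.index[:2]) == {"A6m_L", "A6m_R"}

    def test_identical_subjects_zero_variance(self, study_atlas):
        t = ck.generate_template(ck.default_config(seed=13))
        ids = study_atlas.retained_ids
        subjects = [
            ck.Subject(f"s{k}", ck.GROUPS[k % 3],
                       {w: ck.ConnectomeMatrix(f"s{k}", w,
                                               t[w].values.copy(), ids)
                        for w in ck.WEIGHTINGS})
            for k in range(6)
        ]
        cohort = ck.StudyCohort(subjects, study_atlas)
        mask = ck.consistency_mask(cohort)
        gdf, ndf = ck.compute_all(cohort, mask, weightings=("binary", "FA"))
        assert gdf.groupby("weighting")["global_efficiency"].std().max() == 0
        assert (ndf.groupby(["weighting", "node"])["nodal_efficiency"]
                .std().max() == 0)

    def test_complete_support_binary_efficiency_one(self, study_atlas):
        cfg = ck.default_config(seed=14, n_per_group=2, edge_density=1.0,
                                hub_dropout={g: 0.0 for g in ck.GROUPS})
        cohort = ck.generate_cohort(cfg)
        mask = ck.consistency_mask(cohort)
        gdf, _ = ck.compute_all(cohort, mask, weightings=("binary",))
        assert np.all(gdf["global_efficiency"] == 1.0)
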