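"""Ollivier-Ricci curvature: transport solver, closed forms, invariants."""

from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from riccirank.curvature import (
    compute_curvature,
    edge_curvature,
    ground_distance,
    neighbor_measure,
    scalar_curvature,
    wasserstein1,
    wasserstein1_assignment,
)

from conftest import random_connected_weighted_graph


def frac_measure(G, x):
    """Neighbor measure with exact rational masses (integer weights required)."""
    nbrs = sorted(G.neighbors(x))
    w = [Fraction(G[x][z]["weight"]) for z in nbrs]
    d = sum(w)
    return nbrs, [wi / d for wi in w]


class TestGroundDistance:
    def test_hop_counts_on_path(self):
        G = nx.path_graph(["a", "b", "c"])
        d = ground_distance(G)
        assert d["a"]["c"] == 2
        assert d["a"]["a"] == 0
        assert d["a"]["b"] == 1

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(7)
        G = random_connected_weighted_graph(rng)
        d = ground_distance(G)
        nodes = list(G.nodes)
        for x in nodes:
            for y in nodes:
                assert d[x][y] == d[y][x]
                for z in nodes:
                    assert d[x][y] <= d[x][z] + d[z][y]


class TestWasserstein:
    def test_identical_measures_cost_zero(self, weighted_triangle):
        d = ground_distance(weighted_triangle)
        mu = neighbor_measure(weighted_triangle, "a")
        assert wasserstein1(mu, mu, d) == pytest.approx(0.0, abs=1e-12)

    def test_point_masses_cost_is_distance(self):
        G = nx.path_graph([0, 1, 2, 3])
        d = ground_distance(G)
        cost = wasserstein1(([0], np.array([1.0])), ([3], np.array([1.0])), d)
        assert cost == pytest.approx(3.0)

    def test_triangle_half_unit_cost(self, weighted_triangle):
        # mu_a = {b:1/2, c:1/2}, mu_b = {a:1/2, c:1/2}: half the mass moves one hop
        d = ground_distance(weighted_triangle)
        mu_a = neighbor_measure(weighted_triangle, "a")
        mu_b = neighbor_measure(weighted_triangle, "b")
        assert wasserstein1(mu_a, mu_b, d) == pytest.approx(0.5, abs=1e-9)
        oracle = wasserstein1_assignment(
            frac_measure(weighted_triangle, "a"), frac_measure(weighted_triangle, "b"), d
        )
        assert oracle == pytest.approx(0.5, abs=1e-12)

    def test_unnormalized_measure_rejected(self, weighted_triangle):
        d = ground_distance(weighted_triangle)
        with pytest.raises(ValueError):
            wasserstein1((["b"], np.array([0.7])), (["a"], np.array([1.0])), d)

    def test_plan_marginals_match(self):
        rng = np.random.default_rng(11)
        G = random_connected_weighted_graph(rng)
        d = ground_distance(G)
        x, y = next(iter(G.edges))
        mu_x, mu_y = neighbor_measure(G, x), neighbor_measure(G, y)
        _, plan = wasserstein1(mu_x, mu_y, d, return_plan=True)
        np.testing.assert_allclose(plan.sum(axis=1), mu_x[1], atol=1e-9)
        np.testing.assert_allclose(plan.sum(axis=0), mu_y[1], atol=1e-9)
        assert (plan >= -1e-12).all()

    def test_lp_matches_assignment_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            G = random_connected_weighted_graph(rng, max_degree=5, integer_weights=True)
            d = ground_distance(G)
            edges = sorted(G.edges)
            x, y = edges[int(rng.integers(len(edges)))]
            cost_lp = wasserstein1(neighbor_measure(G, x), neighbor_measure(G, y), d)
            cost_as = wasserstein1_assignment(frac_measure(G, x), frac_measure(G, y), d)
            assert cost_lp == pytest.approx(cost_as, abs=1e-9)


class TestEdgeCurvature:
    def test_triangle_edges_half(self, weighted_triangle):
        for e in weighted_triangle.edges:
            assert edge_curvature(weighted_triangle, e) == pytest.approx(0.5, abs=1e-9)

    def test_path_edge_zero(self):
        G = nx.path_graph(["a", "b", "c"])
        assert edge_curvature(G, ("a", "b")) == pytest.approx(0.0, abs=1e-9)

    def test_four_cycle_zero(self):
        G = nx.cycle_graph(4)
        for e in G.edges:
            assert edge_curvature(G, e) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("n", range(3, 9))
    def test_complete_graph_closed_form(self, n):
        G = nx.complete_graph(n)
        expected = (n - 2) / (n - 1)
        for k in compute_curvature(G).values():
            assert k == pytest.approx(expected, abs=1e-9)

    def test_missing_edge_rejected(self, weighted_triangle):
        with pytest.raises(ValueError):
            edge_curvature(nx.path_graph([0, 1, 2]), (0, 2))

    def test_symmetry_and_bounds_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            G = random_connected_weighted_graph(rng)
            d = ground_distance(G)
            for x, y in G.edges:
                k_xy = edge_curvature(G, (x, y), d)
                k_yx = edge_curvature(G, (y, x), d)
                assert k_xy == pytest.approx(k_yx, abs=1e-9)
                assert -2.0 - 1e-9 <= k_xy <= 1.0 + 1e-9

    def test_weight_locality(self):
        # perturbing one edge weight only moves curvatures whose measures see it
        rng = np.random.default_rng(19)
        G = random_connected_weighted_graph(rng, n_lo=10, n_hi=12)
        base = compute_curvature(G)
        u, v = sorted(G.edges)[0]
        H = G.copy()
        H[u][v]["weight"] *= 1.5
        pert = compute_curvature(H)
        touched = {x for x in (u, v)} | set(G.neighbors(u)) | set(G.neighbors(v))
        for (a, b), k in base.items():
            if a not in touched and b not in touched:
                assert pert[(a, b)] == pytest.approx(k, abs=1e-9)

    def test_weighted_ground_distance_mode(self, weighted_triangle):
        # with unit weights the two modes coincide
        hop = compute_curvature(weighted_triangle, "hop")
        wtd = compute_curvature(weighted_triangle, "weighted")
        for e in hop:
            assert hop[e] == pytest.approx(wtd[e], abs=1e-9)
        with pytest.raises(ValueError):
            compute_curvature(weighted_triangle, "nope")

    def test_disconnected_graph_rejected(self):
        G = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError):
            compute_curvature(G)


class TestScalarCurvature:
    def test_single_edge_graph_zero(self):
        G = nx.Graph([(0, 1)])
        ec = compute_curvature(G)
        assert ec[(0, 1)] == pytest.approx(0.0)
        S = scalar_curvature(G, ec)
        assert S[0] == pytest.approx(0.0) and S[1] == pytest.approx(0.0)

    def test_triangle_node_sum(self, weighted_triangle):
        ec = compute_curvature(weighted_triangle)
        S = scalar_curvature(weighted_triangle, ec)
        for v in weighted_triangle.nodes:
            assert S[v] == pytest.approx(1.0, abs=1e-9)

    def test_equals_incident_edge_sum(self):
        rng = np.random.default_rng(3)
        G = random_connected_weighted_graph(rng)
        ec = compute_curvature(G)
        S = scalar_curvature(G, ec)
        for x in G.nodes:
            total = sum(
                ec[tuple(sorted((x, y)))] for y in G.neighbors(x)
            )
            assert S[x] == pytest.approx(total, abs=1e-12)

    def test_missing_curvature_rejected(self):
        G = nx.path_graph(3)
        with pytest.raises(KeyError):
            scalar_curvature(G, {(0, 1): 0.0})
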