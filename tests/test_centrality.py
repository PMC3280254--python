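"""Centrality indexes against exhaustive geodesic-enumeration oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from acanthonet import (
    compute_centralities,
    network_stats,
    normalize_to_max,
    ratio_to_average,
    scatter_table,
)

from .conftest import brute_force_geodesics, graph_from_edges, random_connected_graph


def oracle_centralities(g):
    """Betweenness / stress / centroid by brute force.

    Geodesics come from exhaustive simple-path enumeration; gamma terms
    from the all-pairs distance dict of networkx.  Fully independent of
    the optimized implementation.
    """
    nodes = sorted(g.nodes)
    dist = dict(nx.all_pairs_shortest_path_length(g.graph))
    bet = {v: 0.0 for v in nodes}
    stress = {v: 0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        paths = brute_force_geodesics(g, s, t)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            stress[v] += through
            bet[v] += through / len(paths)
    centroid = {}
    for v in nodes:
        best = math.inf
        for w in nodes:
            if w == v:
                continue
            gamma_v = sum(
                1 for u in nodes
                if u not in (v, w) and dist[u][v] < dist[u][w]
            )
            gamma_w = sum(
                1 for u in nodes
                if u not in (v, w) and dist[u][w] < dist[u][v]
            )
            best = min(best, gamma_v - gamma_w)
        centroid[v] = best
    return bet, stress, centroid


class TestAgainstOracles:
    def test_path_p3(self):
        t = compute_centralities(graph_from_edges([("a", "b"), ("b", "c")]))
        assert t.score("b", "betweenness") == 1.0
        assert t.score("b", "stress") == 1
        assert t.score("a", "betweenness") == 0.0

    def test_star_k13_centroid(self):
        g = graph_from_edges([("hub", x) for x in "abc"])
        t = compute_centralities(g)
        assert t.score("hub", "centroid") == 2
        assert t.score("a", "centroid") == -2

    def test_random_graphs_match_brute_force(self, rng):
        for _ in range(25):
            g = random_connected_graph(rng, n_max=9)
            t = compute_centralities(g)
            bet, stress, centroid = oracle_centralities(g)
            for v in sorted(g.nodes):
                assert t.score(v, "betweenness") == pytest.approx(bet[v])
                assert t.score(v, "stress") == stress[v]
                assert t.score(v, "centroid") == centroid[v]

    def test_distance_indexes_match_networkx(self, rng):
        for _ in range(10):
            g = random_connected_graph(rng, n_max=10)
            t = compute_centralities(g)
            ecc = nx.eccentricity(g.graph)
            n = g.number_of_nodes()
            for v in sorted(g.nodes):
                assert t.score(v, "eccentricity") == pytest.approx(1 / ecc[v])
                total = sum(nx.single_source_shortest_path_length(g.graph, v).values())
                assert t.score(v, "closeness") == pytest.approx(1 / total)
                assert t.score(v, "degree") == g.degree(v)
                rad = sum(
                    t.diameter + 1 - d
                    for u, d in nx.single_source_shortest_path_length(g.graph, v).items()
                    if u != v
                )
                assert t.score(v, "radiality") == pytest.approx(rad / (n - 1))

    def test_stress_conservation(self, rng):
        """Total stress equals sum over geodesics of interior length."""
        for _ in range(10):
            g = random_connected_graph(rng, n_max=8)
            t = compute_centralities(g)
            total = 0
            for s, tt in itertools.combinations(sorted(g.nodes), 2):
                for p in brute_force_geodesics(g, s, tt):
                    total += len(p) - 2
            assert int(t.df["stress"].sum()) == total

    def test_centroid_antisymmetry_by_construction(self, rng):
        """f(v,w) = -f(w,v): mutual wins cancel over all pairs."""
        g = random_connected_graph(rng, n_max=8)
        nodes = sorted(g.nodes)
        dist = dict(nx.all_pairs_shortest_path_length(g.graph))
        for v, w in itertools.combinations(nodes, 2):
            gamma_v = sum(1 for u in nodes if u not in (v, w) and dist[u][v] < dist[u][w])
            gamma_w = sum(1 for u in nodes if u not in (v, w) and dist[u][w] < dist[u][v])
            assert (gamma_v - gamma_w) == -(gamma_w - gamma_v)

    def test_betweenness_cross_checked_against_networkx(self):
        """Independent library route agrees on a realistic-size network."""
        from acanthonet import generate_interactome

        g = generate_interactome(300, rng_seed=0)
        t = compute_centralities(g)
        ref = nx.betweenness_centrality(g.graph, normalized=False)
        assert max(abs(t.score(v, "betweenness") - ref[v]) for v in g.nodes) < 1e-8

    def test_vertex_transitive_graph_uniform_scores(self):
        c6 = graph_from_edges([(f"n{i}", f"n{(i + 1) % 6}") for i in range(6)])
        t = compute_centralities(c6)
        for idx in t.df.columns:
            assert t.df[idx].nunique() == 1

    def test_disconnected_scored_per_component(self):
        g = graph_from_edges([("a", "b"), ("b", "c"), ("x", "y")])
        t = compute_centralities(g)
        assert t.score("b", "betweenness") == 1.0
        assert t.score("x", "eccentricity") == 1.0  # within its component
        assert t.diameter == 2

    def test_single_node_degenerate(self):
        g = graph_from_edges([], extra_nodes=["solo"])
        t = compute_centralities(g)
        assert t.score("solo", "degree") == 0
        assert t.score("solo", "closeness") == 0.0
        assert "solo" in t.degenerate


class TestRatios:
    def test_cycle_ratios_all_one(self):
        c6 = graph_from_edges([(f"n{i}", f"n{(i + 1) % 6}") for i in range(6)])
        t = compute_centralities(c6)
        ratios = ratio_to_average(t, "n0")
        for idx in ("degree", "eccentricity", "closeness", "radiality", "stress"):
            assert ratios[idx] == pytest.approx(1.0)
        norm = normalize_to_max(t, "n0")
        assert norm["degree"] == pytest.approx(1.0)

    def test_star_center_betweenness_ratio_closed_form(self):
        n_leaves = 8
        g = graph_from_edges([("hub", f"l{i}") for i in range(n_leaves)])
        t = compute_centralities(g)
        # hub lies on every leaf pair's unique geodesic
        hub_bet = n_leaves * (n_leaves - 1) / 2
        assert t.score("hub", "betweenness") == pytest.approx(hub_bet)
        mean = hub_bet / (n_leaves + 1)
        assert ratio_to_average(t, "hub")["betweenness"] == pytest.approx(hub_bet / mean)

    def test_zero_mean_yields_sentinel(self):
        g = graph_from_edges([("a", "b")])
        t = compute_centralities(g)
        assert math.isnan(ratio_to_average(t, "a")["betweenness"])

    def test_ratio_invariant_to_pair_ordering_convention(self, rng):
        """Doubling betweenness/stress (ordered pairs) leaves ratios fixed."""
        g = random_connected_graph(rng, n_max=9)
        t = compute_centralities(g)
        doubled = t.df["betweenness"] * 2
        v = sorted(g.nodes)[0]
        if t.df["betweenness"].mean() > 0:
            assert ratio_to_average(t, v)["betweenness"] == pytest.approx(
                doubled[v] / doubled.mean()
            )


class TestNetworkStats:
    def test_complete_k14(self):
        g = graph_from_edges(
            [(f"k{i}", f"k{j}") for i in range(14) for j in range(i + 1, 14)]
        )
        s = network_stats(g)
        assert s["average_shortest_path"] == pytest.approx(1.0)
        assert s["clustering_coefficient"] == pytest.approx(1.0)
        assert s["neighborhood_connectivity"] == pytest.approx(13.0)
        assert s["density"] == pytest.approx(1.0)

    def test_path_p3(self):
        s = network_stats(graph_from_edges([("a", "b"), ("b", "c")]))
        assert s["average_shortest_path"] == pytest.approx(4 / 3)
        assert s["clustering_coefficient"] == 0.0

    def test_integer_rounded_report_mode(self):
        g = graph_from_edges([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        s = network_stats(g, integer_rounded=True)
        assert all(float(v).is_integer() for v in s.values())


class TestScatterTable:
    def test_two_node_graph_two_rows(self):
        t = compute_centralities(graph_from_edges([("a", "b")]))
        rows = scatter_table(t, "centroid", "betweenness")
        assert len(rows) == 2

    def test_symmetric_graph_no_flags(self):
        c6 = graph_from_edges([(f"n{i}", f"n{(i + 1) % 6}") for i in range(6)])
        rows = scatter_table(compute_centralities(c6), "centroid", "betweenness")
        assert not rows["centroid_above_mean"].any()
        assert not rows["betweenness_above_mean"].any()

    def test_hub_flagged_on_both_axes(self):
        g = graph_from_edges([("hub", f"l{i}") for i in range(5)])
        rows = scatter_table(compute_centralities(g), "centroid", "betweenness")
        hub = rows[rows["node"] == "hub"].iloc[0]
        assert hub["centroid_above_mean"] and hub["betweenness_above_mean"]

    def test_unknown_index_raises(self):
        t = compute_centralities(graph_from_edges([("a", "b")]))
        with pytest.raises(KeyError):
            scatter_table(t, "pagerank", "degree")
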