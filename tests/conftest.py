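"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import random

import networkx as nx
import pytest

from acanthonet import Interactome


def graph_from_edges(edges, extra_nodes=()):
    """Build an Interactome from an edge list plus optional isolated nodes."""
    g = Interactome()
    for n in extra_nodes:
        g.add_node(n)
    for a, b in edges:
        g.add_node(a)
        g.add_node(b)
        g.add_edge(a, b)
    return g


def random_connected_graph(rng: random.Random, n_max: int = 10) -> Interactome:
    """Small random connected graph (spanning tree plus extra edges)."""
    n = rng.randint(2, n_max)
    names = [f"n{i:02d}" for i in range(n)]
    edges = set()
    for i in range(1, n):
        j = rng.randrange(i)
        edges.add((names[j], names[i]))
    extra = rng.randint(0, n * (n - 1) // 2 - (n - 1))
    pairs = [
        (a, b) for a, b in itertools.combinations(names, 2)
        if (a, b) not in edges
    ]
    rng.shuffle(pairs)
    edges.update(pairs[:extra])
    return graph_from_edges(sorted(edges))


def brute_force_geodesics(g: Interactome, s: str, t: str) -> list[tuple[str, ...]]:
    """All shortest s-t paths by exhaustive simple-path enumeration.

    Independent of the predecessor-set implementation under test: uses a
    plain DFS over all simple paths and keeps the minimal length.
    """
    if s == t:
        return [(s,)]
    best: list[tuple[str, ...]] = []
    best_len = [float("inf")]

    def dfs(path, seen):
        u = path[-1]
        if len(path) - 1 > best_len[0]:
            return
        for v in g.graph.neighbors(u):
            if v == t:
                length = len(path)
                if length < best_len[0]:
                    best_len[0] = length
                    best.clear()
                if length == best_len[0]:
                    best.append(tuple(path) + (t,))
            elif v not in seen:
                seen.add(v)
                path.append(v)
                dfs(path, seen)
                path.pop()
                seen.discard(v)

    dfs([s], {s})
    return sorted(best)


@pytest.fixture(scope="session")
def default_pair():
    """One paired synthetic scenario at the pipeline's default settings."""
    from acanthonet import paired_scenarios

    return paired_scenarios(n=500, rng_seed=7)


@pytest.fixture
def rng():
    return random.Random(20240917)
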