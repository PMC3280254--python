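"""Set algebra on interactomes.

First-neighbor expansion, union, edge-wise intersection, induced
subgraphs and largest-component extraction: the primitive moves used to
combine per-condition disease sub-networks into a shared interactomic
space (union of a geodesic network with the first-neighbor expansion of
its probe set, then intersection across conditions).
"""

from __future__ import annotations

import logging

import networkx as nx

from .interactome_io import Interactome, connected_components

logger = logging.getLogger("acanthonet")


class NoSeedError(ValueError):
    """Raised when none of the requested seed nodes exists in the graph."""


def induced_subgraph(g: Interactome, nodes) -> Interactome:
    """Induced subgraph on ``nodes`` (unknown nodes silently ignored)."""
    keep = set(nodes) & g.nodes
    sub = Interactome()
    for n in sorted(keep):
        sub.add_node(n)
    for a, b in g.graph.subgraph(keep).edges:
        sub.add_edge(a, b, **g.graph.edges[a, b])
    return sub


def first_neighbor_expand(g: Interactome, seeds) -> Interactome:
    """Induced subgraph on ``seeds`` plus all their direct interactors.

    Seeds missing from the graph are logged and skipped; if no seed is
    present a :class:`NoSeedError` is raised.
    """
    seeds = set(seeds)
    present = seeds & g.nodes
    missing = seeds - present
    if missing:
        logger.warning("first_neighbor_expand: %d seed(s) absent: %s",
                       len(missing), sorted(missing)[:10])
    if not present:
        raise NoSeedError("none of the seed nodes is present in the graph")
    reach = set(present)
    for s in present:
        reach |= g.neighbors(s)
    return induced_subgraph(g, reach)


def union(g1: Interactome, g2: Interactome) -> Interactome:
    """Node- and edge-set union; metadata conflicts resolve first-wins."""
    out = Interactome()
    for g in (g1, g2):
        for n in g.graph.nodes:
            out.add_node(n)
    for g in (g1, g2):
        for a, b in g.graph.edges:
            if out.has_edge(a, b):
                if g.graph.edges[a, b] and g.graph.edges[a, b] != out.edge_meta(a, b):
                    logger.debug("union: metadata conflict on edge (%s, %s); first wins", a, b)
                continue
            out.add_edge(a, b, **g.graph.edges[a, b])
    return out


def intersect(g1: Interactome, g2: Interactome, keep: str = "all") -> Interactome:
    """Edge-wise intersection: an edge survives only if present in both.

    The node set is the endpoints of surviving edges (a protein with no
    shared interaction carries no topological information here).
    ``keep="largest_component"`` retains only the biggest connected
    component of the result.
    """
    if keep not in ("all", "largest_component"):
        raise ValueError(f"unknown keep mode {keep!r}")
    out = Interactome()
    for a, b in g1.graph.edges:
        if g2.has_edge(a, b):
            out.add_node(a)
            out.add_node(b)
            out.add_edge(a, b, **g1.graph.edges[a, b])
    if out.number_of_edges() == 0:
        logger.warning("intersect: empty intersection")
    if keep == "largest_component":
        out = largest_component(out)
    return out


def largest_component(g: Interactome) -> Interactome:
    """Induced subgraph on the largest connected component.

    Ties break toward the component containing the lexicographically
    smallest node; an empty graph maps to an empty graph.
    """
    comps = connected_components(g)
    if not comps:
        return Interactome()
    return induced_subgraph(g, comps[0])
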