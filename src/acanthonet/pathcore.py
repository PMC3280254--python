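"""All shortest paths via predecessor sets, and seed-to-probe sub-networks.

Classical single-source shortest-path algorithms keep one predecessor per
node and therefore recover a single geodesic.  Here each node keeps a
*set* of predecessors: p is a predecessor of n iff p immediately precedes
n on at least one shortest path from the source.  The predecessor sets
form a DAG from which every geodesic can be enumerated, and the geodesic
count sigma satisfies ``sigma[n] = sum(sigma[p] for p in preds[n])``.

On the unweighted interaction graphs analysed here the Dijkstra scheme
specializes to breadth-first search; a weighted variant is kept behind
the same contract for generality.

``probe_network`` builds the disease sub-network: the union of all
geodesics from a seed protein (e.g. a disease gene product) to a probe
set of differentially phosphorylated proteins.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

from .interactome_io import Interactome

INF = math.inf

#: default ceiling on enumerated geodesics (predecessor DAGs can encode
#: exponentially many paths)
DEFAULT_PATH_CAP = 10_000


@dataclass
class PathResult:
    """Single-source geodesic structure.

    dist
        geodesic distance from ``source`` (``inf`` if unreachable).
    preds
        predecessor sets; together they form the shortest-path DAG.
    sigma
        number of distinct geodesics from ``source`` (0 if unreachable).
    """

    source: str
    dist: dict[str, float]
    preds: dict[str, set[str]]
    sigma: dict[str, int]

    def reachable(self) -> set[str]:
        return {n for n, d in self.dist.items() if d < INF}


@dataclass
class PathSet:
    """Enumerated geodesics between one source/target pair."""

    paths: list[tuple[str, ...]] = field(default_factory=list)
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.paths)


class EmptyNetworkError(ValueError):
    """Raised when a sub-network construction yields nothing."""


def all_shortest_from(
    g: Interactome, source: str, weight: str | None = None
) -> PathResult:
    """Compute distances, predecessor sets and geodesic counts from ``source``.

    ``weight=None`` (the default, and the only case the pipeline uses)
    runs breadth-first search; a non-None edge-attribute name switches to
    a Dijkstra traversal with the same predecessor-set bookkeeping.
    Neighbor iteration is lexicographic so results are reproducible.
    """
    if not g.has_node(source):
        raise KeyError(f"source node {source!r} not in graph")
    dist: dict[str, float] = {n: INF for n in g.graph.nodes}
    preds: dict[str, set[str]] = {n: set() for n in g.graph.nodes}
    sigma: dict[str, int] = {n: 0 for n in g.graph.nodes}
    dist[source] = 0
    sigma[source] = 1

    if weight is None:
        frontier = [source]
        while frontier:
            nxt: list[str] = []
            for u in frontier:
                du = dist[u]
                for v in sorted(g.graph.neighbors(u)):
                    if dist[v] == INF:
                        dist[v] = du + 1
                        nxt.append(v)
                    if dist[v] == du + 1:
                        preds[v].add(u)
                        sigma[v] += sigma[u]
            frontier = nxt
    else:
        done: set[str] = set()
        heap: list[tuple[float, str]] = [(0.0, source)]
        while heap:
            du, u = heapq.heappop(heap)
            if u in done:
                continue
            done.add(u)
            for v in sorted(g.graph.neighbors(u)):
                w = float(g.graph.edges[u, v].get(weight, 1.0))
                if w < 0:
                    raise ValueError("negative edge weights are not supported")
                dv = du + w
                if dv < dist[v]:
                    dist[v] = dv
                    preds[v] = {u}
                    sigma[v] = sigma[u]
                    heapq.heappush(heap, (dv, v))
                elif dv == dist[v] and v not in done:
                    preds[v].add(u)
                    sigma[v] += sigma[u]
    return PathResult(source=source, dist=dist, preds=preds, sigma=sigma)


def _on_path_nodes(pr: PathResult, target: str) -> set[str]:
    """Nodes lying on at least one source->target geodesic."""
    if pr.dist.get(target, INF) == INF:
        return set()
    seen = {target}
    stack = [target]
    while stack:
        n = stack.pop()
        for p in pr.preds[n]:
            if p not in seen:
                seen.add(p)
                stack.append(p)
    return seen


def enumerate_paths(
    pr: PathResult, target: str, cap: int = DEFAULT_PATH_CAP
) -> PathSet:
    """List geodesics source->target in lexicographic order, up to ``cap``.

    Returns exactly ``min(sigma[target], cap)`` paths; ``truncated`` is
    set iff the cap cut the enumeration short.  An unreachable target
    yields an empty, non-truncated PathSet.
    """
    if target not in pr.dist:
        raise KeyError(f"target node {target!r} unknown to this PathResult")
    if cap < 1:
        raise ValueError("cap must be a positive integer")
    if pr.dist[target] == INF:
        return PathSet()
    on_path = _on_path_nodes(pr, target)
    # forward successor lists restricted to the geodesic DAG of this pair
    succ: dict[str, list[str]] = {n: [] for n in on_path}
    for n in on_path:
        for p in pr.preds[n]:
            succ[p].append(n)
    for n in succ:
        succ[n].sort()

    out: list[tuple[str, ...]] = []
    truncated = False
    path: list[str] = [pr.source]

    def walk(u: str) -> bool:
        nonlocal truncated
        if u == target:
            out.append(tuple(path))
            if len(out) >= cap:
                truncated = pr.sigma[target] > cap
                return False
            return True
        for v in succ[u]:
            path.append(v)
            keep_going = walk(v)
            path.pop()
            if not keep_going:
                return False
        return True

    walk(pr.source)
    return PathSet(paths=out, truncated=truncated)


def pairwise_distance(g: Interactome, a: str, b: str) -> float:
    """Geodesic distance between two proteins; ``inf`` if disconnected."""
    for n in (a, b):
        if not g.has_node(n):
            raise KeyError(f"node {n!r} not in graph")
    if a == b:
        return 0
    dist = {a: 0}
    frontier = [a]
    while frontier:
        nxt = []
        for u in frontier:
            for v in g.graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    if v == b:
                        return dist[v]
                    nxt.append(v)
        frontier = nxt
    return INF


def probe_network(
    g: Interactome,
    seed: str,
    probes: set[str] | list[str],
    mode: str = "path_union",
) -> Interactome:
    """Sub-network linking a seed protein to a phospho-probe set.

    ``path_union`` keeps exactly the nodes and edges lying on at least one
    seed->probe geodesic; ``induced`` keeps the same node set with *all*
    interactome edges among them.  Probes absent from the graph are
    skipped and reported in the result's ``missing_probes`` graph
    attribute; per-probe geodesic distances are annotated in
    ``probe_distances``.
    """
    if mode not in ("path_union", "induced"):
        raise ValueError(f"unknown mode {mode!r}")
    if not g.has_node(seed):
        raise KeyError(f"seed node {seed!r} not in graph")
    probes = set(probes)
    missing = sorted(p for p in probes if not g.has_node(p))
    present = sorted(probes - set(missing))

    pr = all_shortest_from(g, seed)
    reachable = [p for p in present if pr.dist[p] < INF]
    if not reachable:
        raise EmptyNetworkError(
            f"no probe reachable from seed {seed!r} "
            f"({len(missing)} missing, {len(present)} present)"
        )

    nodes: set[str] = {seed}
    edges: set[tuple[str, str]] = set()
    for p in reachable:
        on_path = _on_path_nodes(pr, p)
        nodes |= on_path
        for n in on_path:
            for q in pr.preds[n]:
                edges.add(tuple(sorted((q, n))))

    sub = Interactome()
    for n in sorted(nodes):
        sub.add_node(n)
    if mode == "path_union":
        for a, b in sorted(edges):
            sub.add_edge(a, b, **g.graph.edges[a, b])
    else:  # induced: all interactome edges among geodesic nodes
        for a, b in g.graph.subgraph(nodes).edges:
            sub.add_edge(a, b, **g.graph.edges[a, b])
    sub.graph.graph["seed"] = seed
    sub.graph.graph["probe_distances"] = {p: int(pr.dist[p]) for p in reachable}
    sub.graph.graph["probe_path_counts"] = {p: pr.sigma[p] for p in reachable}
    sub.graph.graph["missing_probes"] = missing
    sub.graph.graph["unreachable_probes"] = sorted(set(present) - set(reachable))
    return sub
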