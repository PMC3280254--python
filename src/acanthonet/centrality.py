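"""Node centrality profiling: seven indexes plus whole-network statistics.

Definitions (n = number of nodes, d = geodesic distance, sigma_st the
number of s-t geodesics, sigma_st(v) those passing through v, Delta the
diameter of the component):

* degree(v)        -- neighbor count
* eccentricity(v)  -- 1 / max_w d(v, w)          (reciprocal convention:
  higher = more central)
* closeness(v)     -- 1 / sum_w d(v, w)
* radiality(v)     -- sum_w (Delta + 1 - d(v, w)) / (n - 1)
* stress(v)        -- sum over unordered pairs s < t (s,t != v) of sigma_st(v)
* betweenness(v)   -- same sum, each pair weighted sigma_st(v) / sigma_st
* centroid(v)      -- min over w != v of f(v, w) = gamma_v(w) - gamma_w(v),
  where gamma_v(w) counts nodes strictly closer to v than to w (nodes
  equidistant from v and w count in neither).  Positive centroid marks
  nodes that organize modules.

Stress and betweenness sum over *unordered* pairs; implementations in
the wild differ by a factor of two, and every ratio-to-average output is
insensitive to that choice.  Disconnected inputs are scored per
component (cross-component distances excluded, with a warning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

from .interactome_io import Interactome

logger = logging.getLogger("acanthonet")

INDEXES = (
    "degree", "eccentricity", "closeness", "radiality",
    "betweenness", "stress", "centroid",
)

#: sentinel for a ratio whose denominator (index mean) is zero
NOT_DEFINED = float("nan")


@dataclass
class CentralityTable:
    """Per-node scores for the seven indexes plus summary statistics.

    ``df`` is indexed by node with one column per index.  ``summary``
    maps each index to its mean/min/max over nodes; ``diameter`` is the
    maximum geodesic distance (over components, the largest one).
    ``degenerate`` flags single-node components whose reciprocal indexes
    (eccentricity, closeness) are undefined and reported as 0.
    """

    df: pd.DataFrame
    diameter: int
    degenerate: set = field(default_factory=set)

    @property
    def summary(self) -> dict[str, dict[str, float]]:
        return {
            idx: {
                "mean": float(self.df[idx].mean()),
                "min": float(self.df[idx].min()),
                "max": float(self.df[idx].max()),
            }
            for idx in INDEXES
        }

    def score(self, node: str, index: str) -> float:
        return float(self.df.at[node, index])

    def to_tsv(self, stream) -> None:
        out = self.df.copy()
        out.insert(0, "node", out.index)
        out.to_csv(stream, sep="\t", index=False)

    def summary_json(self) -> dict:
        return {"indexes": self.summary, "diameter": self.diameter}


def _distance_matrix(graph: nx.Graph, order: list[str]) -> np.ndarray:
    adj = nx.to_scipy_sparse_array(graph, nodelist=order, format="csr")
    return _csgraph_sp(adj, method="D", directed=False, unweighted=True)


def _brandes_unordered(graph: nx.Graph, order: list[str]):
    """Betweenness and stress over unordered node pairs (endpoints excluded).

    Single-source accumulation: for each source the dependency recursion
    delta(v) = sum_{w: v in preds(w)} sigma_v/sigma_w * (1 + delta(w))
    yields betweenness; the unweighted-count analogue zeta(v) =
    sum_{w: v in preds(w)} (1 + zeta(w)) scaled by sigma_v yields stress.
    Summing over all sources counts each unordered pair twice, so totals
    are halved at the end.
    """
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    bet = np.zeros(n)
    stress2 = np.zeros(n, dtype=np.int64)  # ordered-pair stress (even)
    adj = {u: sorted(graph.neighbors(u)) for u in order}

    for s in order:
        # BFS with predecessor lists and sigma
        dist = {s: 0}
        sigma = {s: 1}
        preds: dict[str, list[str]] = {s: []}
        stack_order: list[str] = []
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                stack_order.append(u)
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        sigma[v] = 0
                        preds[v] = []
                        nxt.append(v)
                    if dist[v] == dist[u] + 1:
                        sigma[v] += sigma[u]
                        preds[v].append(u)
            frontier = nxt
        delta = {v: 0.0 for v in dist}
        zeta = {v: 0 for v in dist}
        for w in reversed(stack_order):
            for p in preds[w]:
                delta[p] += sigma[p] / sigma[w] * (1.0 + delta[w])
                zeta[p] += 1 + zeta[w]
            if w != s:
                bet[idx[w]] += delta[w]
                stress2[idx[w]] += sigma[w] * zeta[w]
    assert np.all(stress2 % 2 == 0)
    return bet / 2.0, stress2 // 2


def _centroid_scores(D: np.ndarray) -> np.ndarray:
    """centroid(v) = min_{w != v} [gamma_v(w) - gamma_w(v)] via numpy.

    gamma_v(w) counts u (u != v, w) with d(u,v) < d(u,w); the u = v term
    (always strictly closer to itself for w != v) is subtracted, and the
    u = w term contributes to neither side.
    """
    n = D.shape[0]
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    gamma = np.empty((n, n), dtype=np.int64)
    for v in range(n):
        gamma[v, :] = (D[:, v][:, None] < D).sum(axis=0)
    off = ~np.eye(n, dtype=bool)
    gamma[off] -= 1  # remove the u = v self term
    f = gamma - gamma.T
    f = np.where(off, f, np.iinfo(np.int64).max)
    return f.min(axis=1)


def compute_centralities(g: Interactome) -> CentralityTable:
    """Score every node of ``g`` on the seven indexes.

    A disconnected input is scored within each connected component (with
    a warning); the reported diameter is the largest component diameter.
    """
    if g.number_of_nodes() == 0:
        return CentralityTable(
            df=pd.DataFrame(columns=list(INDEXES)), diameter=0
        )
    comps = [sorted(c) for c in nx.connected_components(g.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    if len(comps) > 1:
        logger.warning(
            "graph has %d components; centralities computed per component",
            len(comps),
        )
    frames = []
    diameter = 0
    degenerate: set = set()
    for order in comps:
        sub = g.graph.subgraph(order)
        n = len(order)
        if n == 1:
            # path-based and reciprocal indexes undefined; reported as 0
            degenerate.add(order[0])
            frames.append(
                pd.DataFrame(
                    {i: [0.0] for i in INDEXES}, index=order
                ).astype({"degree": int, "stress": int, "centroid": int})
            )
            continue
        D = _distance_matrix(sub, order)
        ecc_raw = D.max(axis=1)
        delta = int(ecc_raw.max())
        diameter = max(diameter, delta)
        bet, stress = _brandes_unordered(sub, order)
        frame = pd.DataFrame(
            {
                "degree": [sub.degree(v) for v in order],
                "eccentricity": 1.0 / ecc_raw,
                "closeness": 1.0 / D.sum(axis=1),
                "radiality": (delta + 1.0 - D).sum(axis=1) / (n - 1.0)
                - (delta + 1.0) / (n - 1.0),  # remove the d(v,v)=0 self term
                "betweenness": bet,
                "stress": stress,
                "centroid": _centroid_scores(D),
            },
            index=order,
        )
        frames.append(frame)
    df = pd.concat(frames)
    df = df.loc[sorted(df.index)]
    return CentralityTable(df=df, diameter=diameter, degenerate=degenerate)


def ratio_to_average(t: CentralityTable, node: str) -> dict[str, float]:
    """Each index score divided by that index's mean over all nodes.

    A zero mean yields a NaN sentinel for that index.
    """
    if node not in t.df.index:
        raise KeyError(f"node {node!r} not in centrality table")
    out: dict[str, float] = {}
    for idx in INDEXES:
        mean = float(t.df[idx].mean())
        out[idx] = float(t.df.at[node, idx]) / mean if mean != 0 else NOT_DEFINED
    return out


def normalize_to_max(t: CentralityTable, node: str) -> dict[str, float]:
    """Scores normalized to the maximal value of each index (0..1 scale)."""
    if node not in t.df.index:
        raise KeyError(f"node {node!r} not in centrality table")
    out: dict[str, float] = {}
    for idx in INDEXES:
        mx = float(t.df[idx].max())
        out[idx] = float(t.df.at[node, idx]) / mx if mx != 0 else NOT_DEFINED
    return out


def network_stats(g: Interactome, integer_rounded: bool = False) -> dict[str, float]:
    """Whole-network topology summary.

    average_shortest_path averages geodesic length over unordered
    reachable pairs; clustering_coefficient is the mean local clustering
    with degree < 2 nodes contributing 0; neighborhood_connectivity is
    the mean over nodes of the mean neighbor degree; density is
    2|E| / (|N|(|N|-1)).  ``integer_rounded`` rounds each statistic to
    the nearest integer (a report mode matching coarse published
    summaries).
    """
    graph = g.graph
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    if n == 1:
        stats = {
            "average_shortest_path": 0.0,
            "clustering_coefficient": 0.0,
            "neighborhood_connectivity": 0.0,
            "density": 0.0,
        }
    else:
        total = 0.0
        pairs = 0
        for comp in nx.connected_components(graph):
            order = sorted(comp)
            if len(order) < 2:
                continue
            D = _distance_matrix(graph.subgraph(order), order)
            iu = np.triu_indices(len(order), k=1)
            total += float(D[iu].sum())
            pairs += len(iu[0])
        avg_sp = total / pairs if pairs else 0.0
        clustering = float(nx.average_clustering(graph, count_zeros=True))
        neigh = nx.average_neighbor_degree(graph)
        nc_vals = [neigh[v] for v in graph.nodes if graph.degree(v) > 0]
        nc = float(np.mean(nc_vals)) if nc_vals else 0.0
        stats = {
            "average_shortest_path": avg_sp,
            "clustering_coefficient": clustering,
            "neighborhood_connectivity": nc,
            "density": float(nx.density(graph)),
        }
    if integer_rounded:
        stats = {k: float(round(v)) for k, v in stats.items()}
    return stats


def scatter_table(t: CentralityTable, x: str, y: str) -> pd.DataFrame:
    """Two-index scatter export: node, scores, strict above-mean flags.

    This is the tabular form of the centroid-vs-betweenness plot used to
    discretize a network into high/high quadrant candidates.
    """
    for idx in (x, y):
        if idx not in INDEXES:
            raise KeyError(f"unknown centrality index {idx!r}")
    mx, my = float(t.df[x].mean()), float(t.df[y].mean())
    out = pd.DataFrame(
        {
            "node": t.df.index,
            x: t.df[x].to_numpy(),
            y: t.df[y].to_numpy(),
            f"{x}_above_mean": (t.df[x] > mx).to_numpy(),
            f"{y}_above_mean": (t.df[y] > my).to_numpy(),
        }
    ).reset_index(drop=True)
    return out
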