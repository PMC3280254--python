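"""Annotation-driven filtering and over-representation analysis.

Four ingredients of the module-extraction stage:

* a kinase/phosphatase/phospho-state census of a network,
* the dual-centrality filter (keep nodes strictly above the network
  average on each listed index, e.g. centroid AND betweenness),
* GO-category membership filtering (literal, case-folded term match),
* a self-contained hypergeometric over-representation test with
  Benjamini-Hochberg correction, operating on user-supplied term tables
  (no external ontology service involved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import false_discovery_control, hypergeom

from .centrality import INDEXES, CentralityTable
from .interactome_io import Interactome, NodeAttributeTable
from .netalgebra import induced_subgraph

logger = logging.getLogger("acanthonet")


@dataclass
class FilterSpec:
    """Which centrality indexes to threshold and how.

    ``strict_mean`` keeps score > mean (the default; on a vertex-transitive
    graph this correctly selects nothing), ``mean_or_equal`` keeps
    score >= mean.  ``combine="all"`` requires every index to pass,
    ``"any"`` at least one.
    """

    indexes: list[str] = field(default_factory=lambda: ["centroid", "betweenness"])
    threshold: str = "strict_mean"
    combine: str = "all"

    def __post_init__(self) -> None:
        if not self.indexes:
            raise ValueError("FilterSpec.indexes must be non-empty")
        for idx in self.indexes:
            if idx not in INDEXES:
                raise ValueError(f"unknown centrality index {idx!r}")
        if self.threshold not in ("strict_mean", "mean_or_equal"):
            raise ValueError(f"unknown threshold mode {self.threshold!r}")
        if self.combine not in ("all", "any"):
            raise ValueError(f"unknown combine mode {self.combine!r}")


@dataclass
class EnrichmentResult:
    """One term's over-representation statistics.

    k of n query nodes hit the term; K of N background nodes carry it.
    ``p_value`` is the hypergeometric upper tail P(X >= k); ``q_value``
    the Benjamini-Hochberg adjusted value.
    """

    term: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    q_value: float = 1.0


def census(g: Interactome, attrs: NodeAttributeTable) -> dict:
    """Partition network nodes by biochemical activity and phospho state.

    Returns kinase and phosphatase node sets plus hyper- and
    de-phosphorylated nodes mapped to their signed fold-changes; nodes
    absent from ``attrs`` count as unannotated.
    """
    kinases: set[str] = set()
    phosphatases: set[str] = set()
    hyper: dict[str, float] = {}
    dephos: dict[str, float] = {}
    unannotated = 0
    for n in g.graph.nodes:
        if n not in attrs:
            unannotated += 1
            continue
        a = attrs.get(n)
        if a.is_kinase:
            kinases.add(n)
        if a.is_phosphatase:
            phosphatases.add(n)
        if a.phospho_fold_change is not None:
            if a.phospho_fold_change > 0:
                hyper[n] = a.phospho_fold_change
            elif a.phospho_fold_change < 0:
                dephos[n] = a.phospho_fold_change
    return {
        "kinases": kinases,
        "phosphatases": phosphatases,
        "hyperphosphorylated": hyper,
        "dephosphorylated": dephos,
        "unannotated": unannotated,
    }


def centrality_filter(
    g: Interactome, t: CentralityTable, spec: FilterSpec | None = None
) -> Interactome:
    """Induced subgraph on nodes passing the above-average filter."""
    spec = spec or FilterSpec()
    means = {idx: float(t.df[idx].mean()) for idx in spec.indexes}

    def passes(node: str) -> bool:
        checks = []
        for idx in spec.indexes:
            score = t.score(node, idx)
            if spec.threshold == "strict_mean":
                checks.append(score > means[idx])
            else:
                checks.append(score >= means[idx])
        return all(checks) if spec.combine == "all" else any(checks)

    keep = {n for n in g.graph.nodes if n in t.df.index and passes(n)}
    if not keep:
        logger.warning("centrality_filter: no node passes %s", spec)
    return induced_subgraph(g, keep)


def go_filter(
    g: Interactome,
    attrs: NodeAttributeTable,
    terms,
    match: str = "any",
) -> Interactome:
    """Induced subgraph on nodes annotated to the given GO categories.

    Term names compare case-folded and literally (no ontology descendant
    closure).  ``match="any"`` keeps nodes carrying at least one term,
    ``"all"`` only nodes carrying every term.
    """
    if match not in ("any", "all"):
        raise ValueError(f"unknown match mode {match!r}")
    wanted = {t.casefold() for t in terms}
    if not wanted:
        raise ValueError("no GO terms given")

    def passes(node: str) -> bool:
        have = {t.casefold() for t in attrs.get(node).go_terms}
        return bool(wanted & have) if match == "any" else wanted <= have

    return induced_subgraph(g, {n for n in g.graph.nodes if passes(n)})


def enrichment(query, background, term_map) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of annotation terms in a query set.

    For each term with K annotated nodes among the N background nodes and
    k hits among the n query nodes, the upper-tail p-value is

        p = sum_{i=k}^{min(n, K)} C(K, i) C(N-K, n-i) / C(N, n)

    q-values are Benjamini-Hochberg over the tested terms; results come
    back sorted by ascending p (ties by term name).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background set")
    query = set(query)
    if not query <= background:
        raise ValueError("query must be a subset of background")
    N, n = len(background), len(query)
    results: list[EnrichmentResult] = []
    for term in sorted(term_map):
        annotated = set(term_map[term]) & background
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term=term, k=k, n=n, K=K, N=N,
                                        p_value=min(p, 1.0)))
    if results:
        qvals = false_discovery_control([r.p_value for r in results], method="bh")
        for r, q in zip(results, qvals):
            r.q_value = float(min(q, 1.0))
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def enrichment_tsv(results: list[EnrichmentResult], stream) -> None:
    stream.write("term\tk\tn\tK\tN\tp\tq\n")
    for r in results:
        stream.write(
            f"{r.term}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t{r.p_value:.6g}\t{r.q_value:.6g}\n"
        )
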