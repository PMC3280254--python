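"""Two-stage network analysis pipeline.

Stage A (per condition): build the seed-to-probe geodesic network,
profile it with the seven centrality indexes, run the kinase /
phosphatase census, and report ratio-to-average centralities.

Stage B (two conditions): per condition, union the stage-A network with
the first-neighbor expansion of its probe set ("enriched" network);
intersect the two enriched networks edge-wise keeping the largest
connected component; keep nodes with both centroid and betweenness
strictly above the network average; keep nodes annotated to the target
GO categories; report the topology statistics of the surviving module.
A manifest records node/edge counts at every step.

The in-memory entry points (:func:`run_stage_a`, :func:`run_stage_b`)
operate on :class:`DiseaseScenario`-like inputs; :class:`PipelineConfig`
plus :func:`run_from_config` add the file-based interface used by the
command line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate_filter, centrality, netalgebra, pathcore
from .interactome_io import (
    Interactome,
    NodeAttributeTable,
    read_attributes,
    read_network,
    sif_string,
)

logger = logging.getLogger("acanthonet")


@dataclass
class Condition:
    """One disease condition: a seed protein and its phospho-probe set."""

    name: str
    seed: str
    probes: dict[str, float] | set[str]

    def probe_nodes(self) -> set[str]:
        return set(self.probes)


@dataclass
class PipelineConfig:
    """Run parameters; at most two conditions (two for stage B)."""

    interactome: str = ""
    attributes: str = ""
    conditions: list[dict] = field(default_factory=list)
    mode: str = "path_union"
    filter_indexes: list[str] = field(default_factory=lambda: ["centroid", "betweenness"])
    filter_threshold: str = "strict_mean"
    go_terms: list[str] = field(default_factory=list)
    go_match: str = "any"
    out_dir: str = "acanthonet_out"
    path_cap: int = pathcore.DEFAULT_PATH_CAP
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.conditions) <= 2:
            raise ValueError("pipeline needs one condition (stage A) or two (stage A+B)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class StageAResult:
    condition: str
    network: Interactome
    table: centrality.CentralityTable
    census: dict
    ratios: dict[str, dict[str, float]]
    probe_distances: dict[str, int]


@dataclass
class StageBResult:
    enriched: dict[str, Interactome]
    intersected: Interactome
    filtered: Interactome
    module: Interactome
    module_stats: dict[str, float]
    manifest: dict


def run_stage_a(
    g: Interactome,
    condition: Condition,
    attrs: NodeAttributeTable | None = None,
    mode: str = "path_union",
    ratio_nodes: tuple[str, ...] = (),
    distance_pairs: tuple[tuple[str, str], ...] = (),
) -> StageAResult:
    """Reconstruct and profile one condition's seed-to-probe network."""
    net = pathcore.probe_network(g, condition.seed, condition.probe_nodes(), mode=mode)
    table = centrality.compute_centralities(net)
    cens = (
        annotate_filter.census(net, attrs)
        if attrs is not None
        else {"kinases": set(), "phosphatases": set(),
              "hyperphosphorylated": {}, "dephosphorylated": {}, "unannotated": len(net)}
    )
    ratios = {
        node: centrality.ratio_to_average(table, node)
        for node in ratio_nodes
        if node in table.df.index
    }
    extra_dist = {
        (a, b): pathcore.pairwise_distance(net, a, b)
        for a, b in distance_pairs
        if net.has_node(a) and net.has_node(b)
    }
    result = StageAResult(
        condition=condition.name,
        network=net,
        table=table,
        census=cens,
        ratios=ratios,
        probe_distances=dict(net.graph.graph.get("probe_distances", {})),
    )
    if extra_dist:
        result.census["pairwise_distances"] = {f"{a}--{b}": d for (a, b), d in extra_dist.items()}
    return result


def run_stage_b(
    g: Interactome,
    conditions: list[Condition],
    attrs: NodeAttributeTable,
    stage_a: dict[str, StageAResult] | None = None,
    mode: str = "path_union",
    filter_spec: annotate_filter.FilterSpec | None = None,
    go_terms=None,
    go_match: str = "any",
) -> StageBResult:
    """Combine two conditions into the shared filtered kinase module."""
    if len(conditions) != 2:
        raise ValueError("stage B requires exactly two conditions")
    go_terms = list(go_terms or [])
    if not go_terms:
        raise ValueError("stage B requires the target GO categories")
    filter_spec = filter_spec or annotate_filter.FilterSpec()
    manifest: dict = {"steps": []}

    def record(step: str, net: Interactome) -> None:
        manifest["steps"].append(
            {"step": step, "nodes": net.number_of_nodes(), "edges": net.number_of_edges()}
        )
        if net.number_of_nodes() == 0 and "go_filter" not in step and "centrality" not in step:
            raise pathcore.EmptyNetworkError(f"empty network after step {step!r}")

    enriched: dict[str, Interactome] = {}
    for cond in conditions:
        a = (stage_a or {}).get(cond.name) or run_stage_a(g, cond, attrs, mode=mode)
        fn = netalgebra.first_neighbor_expand(g, cond.probe_nodes() & g.nodes)
        enr = netalgebra.union(a.network, fn)
        record(f"{cond.name}:probe_network", a.network)
        record(f"{cond.name}:first_neighbors", fn)
        record(f"{cond.name}:enriched_union", enr)
        enriched[cond.name] = enr

    names = [c.name for c in conditions]
    inter = netalgebra.intersect(enriched[names[0]], enriched[names[1]],
                                 keep="largest_component")
    record("intersected_largest_component", inter)

    table = centrality.compute_centralities(inter)
    filtered = annotate_filter.centrality_filter(inter, table, filter_spec)
    record("centrality_filter", filtered)

    module = annotate_filter.go_filter(filtered, attrs, go_terms, match=go_match)
    record("go_filter", module)

    stats = (
        centrality.network_stats(module) if module.number_of_nodes() else
        {"average_shortest_path": 0.0, "clustering_coefficient": 0.0,
         "neighborhood_connectivity": 0.0, "density": 0.0}
    )
    manifest["module_nodes"] = sorted(module.nodes)
    manifest["module_stats"] = stats
    return StageBResult(
        enriched=enriched,
        intersected=inter,
        filtered=filtered,
        module=module,
        module_stats=stats,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# File-based front end
# ---------------------------------------------------------------------------

def _load_probes(path: str | Path) -> dict[str, float]:
    probes: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        probes[parts[0]] = float(parts[1]) if len(parts) > 1 else 0.0
    return probes


def run_from_config(cfg: PipelineConfig) -> dict:
    """Execute the configured run, writing SIF/TSV outputs and a manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(cfg.interactome) as fh:
        g = read_network(fh)
    attrs = NodeAttributeTable()
    if cfg.attributes:
        with open(cfg.attributes) as fh:
            attrs = read_attributes(fh)
    conditions = [
        Condition(name=c["name"], seed=c["seed"], probes=_load_probes(c["probes"]))
        for c in cfg.conditions
    ]
    manifest: dict = {
        "config": {
            "interactome": cfg.interactome,
            "conditions": [c.name for c in conditions],
            "mode": cfg.mode,
            "filter_indexes": cfg.filter_indexes,
            "go_terms": cfg.go_terms,
            "rng_seed": cfg.rng_seed,
        }
    }
    stage_a: dict[str, StageAResult] = {}
    for cond in conditions:
        res = run_stage_a(g, cond, attrs, mode=cfg.mode)
        stage_a[cond.name] = res
        (out / f"{cond.name}.probe_net.sif").write_text(sif_string(res.network))
        with open(out / f"{cond.name}.centrality.tsv", "w") as fh:
            res.table.to_tsv(fh)
        with open(out / f"{cond.name}.probe_distances.tsv", "w") as fh:
            fh.write("probe\tdistance\tn_shortest_paths\n")
            counts = res.network.graph.graph.get("probe_path_counts", {})
            for p, d in sorted(res.probe_distances.items()):
                fh.write(f"{p}\t{d}\t{counts.get(p, '')}\n")
    if len(conditions) == 2:
        spec = annotate_filter.FilterSpec(
            indexes=list(cfg.filter_indexes), threshold=cfg.filter_threshold
        )
        res_b = run_stage_b(
            g, conditions, attrs, stage_a=stage_a, mode=cfg.mode,
            filter_spec=spec, go_terms=cfg.go_terms, go_match=cfg.go_match,
        )
        for name, net in res_b.enriched.items():
            (out / f"{name}.enriched.sif").write_text(sif_string(net))
        (out / "intersected.sif").write_text(sif_string(res_b.intersected))
        (out / "filtered.sif").write_text(sif_string(res_b.filtered))
        (out / "module.sif").write_text(sif_string(res_b.module))
        manifest.update(res_b.manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
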