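"""Synthetic interactomes and planted disease scenarios.

Real inputs to this pipeline are a large curated protein-interaction
network, a disease seed protein, and a probe set of differentially
phosphorylated proteins.  This module fabricates statistically similar
stand-ins so that every pipeline stage is testable without any download:

* a sparse undirected background interactome with heavy-tailed degrees
  (preferential attachment by default, at roughly 5 edges per node --
  the sparsity regime of curated mammalian interactomes);
* a planted *kinase module*: a clique of kinase-flagged nodes carrying
  two target GO categories, wired as first neighbors of the disease
  seed, each with a private "adapter" interactor through which distal
  probes connect (mimicking kinases that both interact with the disease
  protein and act on the observed phosphoproteome);
* per-condition probe sets at controlled geodesic distances from the
  seed, with signed fold-changes of magnitude >= 2 (the usual twofold
  abundance-change cut-off).

Because the module is a clique of first neighbors of the seed whose
adapters relay the probes, the full two-stage analysis provably tends to
recover exactly the planted module from a pair of scenarios sharing it:
clique edges survive the cross-condition intersection via the probes'
first-neighbor expansions, adapter pendants give every module node
above-average betweenness, and only module nodes carry the target GO
labels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .interactome_io import (
    Interactome,
    NodeAttributeTable,
    NodeAttributes,
    sif_string,
    write_attributes,
)

MODELS = ("duplication_divergence", "preferential_attachment", "erdos_renyi")

#: GO categories carried by the planted module (the pipeline's final filter)
TARGET_TERMS = ("erythrocyte development", "neurogenesis")

#: decoy GO categories sprinkled over the background
DECOY_TERMS = (
    "cytoskeleton organization", "vesicle transport", "immune response",
    "apoptotic process", "cell cycle", "ion transport", "rna processing",
    "lipid metabolism", "protein folding", "dna repair",
    "oxidative stress response", "membrane organization",
)

#: distance mix for probe placement: direct kinase substrates at 2 steps
#: from the seed plus more distal targets at 3-4 degrees of separation
DEFAULT_DISTANCE_LAW = {2: 0.4, 3: 0.45, 4: 0.15}


@dataclass
class DiseaseScenario:
    """One condition's synthetic bundle plus its planted ground truth."""

    interactome: Interactome
    seed_node: str
    probe_set: dict[str, float]  # probe -> signed fold-change
    attrs: NodeAttributeTable
    truth: dict = field(default_factory=dict)


def generate_interactome(
    n: int,
    model: str = "preferential_attachment",
    params: dict | None = None,
    rng_seed: int = 0,
) -> Interactome:
    """Generate a simple undirected background interactome.

    Models and their parameters:

    * ``preferential_attachment`` -- Barabasi-Albert, ``m`` edges per new
      node (default 5); heavy-tailed degrees, connected.
    * ``duplication_divergence`` -- gene-duplication model, retention
      probability ``p`` (default 0.3).
    * ``erdos_renyi`` -- homogeneous baseline, edge probability ``p``
      (default chosen to match the preferential-attachment density).

    Identical ``rng_seed`` gives an identical graph.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r} (choose from {MODELS})")
    params = dict(params or {})
    if model == "preferential_attachment":
        m = int(params.pop("m", 5))
        if not 1 <= m < n:
            raise ValueError(f"preferential_attachment requires 1 <= m < n, got m={m}")
        raw = nx.barabasi_albert_graph(n, m, seed=rng_seed)
    elif model == "duplication_divergence":
        p = float(params.pop("p", 0.3))
        if not 0 < p <= 1:
            raise ValueError("duplication_divergence retention p must be in (0, 1]")
        raw = nx.duplication_divergence_graph(n, p, seed=rng_seed)
    else:
        p = float(params.pop("p", min(1.0, 10.0 / n)))
        if not 0 <= p <= 1:
            raise ValueError("erdos_renyi edge probability must be in [0, 1]")
        raw = nx.gnp_random_graph(n, p, seed=rng_seed)
    if params:
        raise ValueError(f"unknown parameters for {model}: {sorted(params)}")
    width = max(4, len(str(n)))
    mapping = {i: f"G{i:0{width}d}" for i in raw.nodes}
    return Interactome.from_graph(nx.relabel_nodes(raw, mapping))


def _fold_change(rng: np.random.Generator) -> float:
    """Signed fold-change: log-normal magnitude truncated below at 2."""
    while True:
        mag = math.exp(rng.normal(1.0, 0.3))
        if mag >= 2.0:
            break
    return mag if rng.random() < 0.5 else -mag


def _draw_distances(rng: np.random.Generator, law: dict[int, float], k: int) -> list[int]:
    ds = sorted(law)
    probs = np.array([law[d] for d in ds], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("distance_law must be a non-negative, non-trivial weighting")
    probs = probs / probs.sum()
    return [int(d) for d in rng.choice(ds, size=k, p=probs)]


def _bfs_distances(g: Interactome, source: str) -> dict[str, int]:
    return nx.single_source_shortest_path_length(g.graph, source)


class _PlantedCore:
    """Shared planted structure: kinase-module clique plus adapters."""

    def __init__(self, module: list[str], adapters: list[str]):
        self.module = module
        self.adapters = adapters


def _plant_core(
    g: Interactome,
    module_size: int,
    rng: np.random.Generator,
) -> _PlantedCore:
    """Promote the top-degree background nodes to a fully connected module.

    Signaling kinases are among the best-connected proteins of curated
    interactomes, so the module is planted on the graph's hubs: the
    ``module_size`` highest-degree nodes, completed into a clique.  Each
    module node additionally gets a private low-degree "adapter"
    interactor, through which distal probes will be relayed.
    """
    if module_size < 2:
        raise ValueError("module_size must be >= 2")
    if module_size > g.number_of_nodes():
        raise ValueError("module_size exceeds number of background nodes")
    ranked = sorted(g.nodes, key=lambda v: (-g.degree(v), v))
    module = ranked[:module_size]
    adapters = [f"ADP{i + 1:02d}" for i in range(module_size)]
    for i, a in enumerate(module):
        for b in module[i + 1:]:
            g.add_edge(a, b, relation="pp")
    for m, a in zip(module, adapters):
        g.add_node(a)
        g.add_edge(m, a, relation="pp")
    return _PlantedCore(module=module, adapters=adapters)


def _attach_condition(
    g: Interactome,
    core: _PlantedCore,
    seed_name: str,
    n_probes: int,
    distance_law: dict[int, float],
    rng: np.random.Generator,
    max_retries: int = 50,
    exclude: set[str] | None = None,
) -> tuple[dict[str, float], dict[str, int]]:
    """Wire one condition: a seed node plus a probe set at drawn distances.

    Probes are background proteins.  Distance-1 probes bind the seed
    directly, distance-2 probes bind module kinases, distance-3 probes
    bind module adapters (assigned round-robin so every adapter relays
    at least one probe when possible), and farther probes are picked
    among nodes already at the requested geodesic distance.
    """
    if g.has_node(seed_name):
        raise ValueError(f"node {seed_name!r} already exists")
    g.add_node(seed_name)
    for m in core.module:
        g.add_edge(seed_name, m, relation="pp")

    planted = set(core.module) | set(core.adapters) | {seed_name} | set(exclude or ())
    dist0 = _bfs_distances(g, seed_name)
    draws = _draw_distances(rng, distance_law, n_probes)
    probes: list[str] = []
    chosen: set[str] = set()

    def pick(min_dist: int) -> str | None:
        cands = [
            v for v, d in dist0.items()
            if d >= min_dist and v not in planted and v not in chosen
        ]
        if not cands:
            return None
        v = str(rng.choice(sorted(cands)))
        chosen.add(v)
        return v

    near = [d for d in draws if d <= 3]
    far = [d for d in draws if d >= 4]

    d2_probes: list[str] = []
    d3_probes: list[str] = []

    def wire_near(p: str, d: int) -> None:
        if d == 1:
            g.add_edge(seed_name, p, relation="pp")
        elif d == 2:
            d2_probes.append(p)
        else:
            d3_probes.append(p)

    for d in near:
        p = pick(d)
        if p is None:
            raise RuntimeError("background graph too small for the requested probe count")
        probes.append(p)
        wire_near(p, d)

    # distal probes: selected at the exact requested geodesic distance;
    # an unachievable distance is redrawn from the full law (bounded),
    # so a law supported only on impossible distances raises with the
    # achievable alternatives listed
    dist_now = _bfs_distances(g, seed_name)
    by_dist: dict[int, list[str]] = {}
    for v, d in dist_now.items():
        if d >= 4 and v not in planted and v not in chosen:
            by_dist.setdefault(d, []).append(v)
    for d in far:
        attempts = 0
        while d >= 4 and not by_dist.get(d):
            attempts += 1
            if attempts > max_retries:
                achievable = sorted([1, 2, 3] + [k for k, vs in by_dist.items() if vs])
                raise RuntimeError(
                    f"no node at distance {d} from {seed_name}; "
                    f"achievable distances: {achievable}"
                )
            d = _draw_distances(rng, distance_law, 1)[0]
        if d <= 3:
            p = pick(d)
            if p is None:
                raise RuntimeError("background graph too small for the requested probe count")
            wire_near(p, d)
        else:
            pool = sorted(by_dist[d])
            p = str(rng.choice(pool))
            by_dist[d].remove(p)
            chosen.add(p)
        probes.append(p)

    # kinase-substrate wiring: distance-2 probes bind module kinases,
    # round-robin so that every module kinase acts on at least one probe
    # (making the whole module part of the probes' first-neighbor space)
    if d2_probes:
        rounds = max(2 * len(d2_probes), len(core.module))
        for i in range(rounds):
            g.add_edge(d2_probes[i % len(d2_probes)],
                       core.module[i % len(core.module)], relation="pp")
    # round-robin adapter assignment: every adapter relays >= 1 probe and
    # every distance-3 probe binds >= 1 adapter
    if d3_probes:
        rounds = max(len(d3_probes), len(core.adapters))
        for i in range(rounds):
            g.add_edge(d3_probes[i % len(d3_probes)],
                       core.adapters[i % len(core.adapters)], relation="pp")

    folds = {p: _fold_change(rng) for p in sorted(probes)}
    achieved = _bfs_distances(g, seed_name)
    distances = {p: int(achieved[p]) for p in probes}
    return folds, distances


def _annotate(
    g: Interactome,
    core: _PlantedCore,
    folds: dict[str, float],
    frac_kinase: float,
    rng: np.random.Generator,
    target_terms=TARGET_TERMS,
) -> NodeAttributeTable:
    attrs = NodeAttributeTable()
    module = set(core.module)
    for n in sorted(g.nodes):
        a = NodeAttributes(approved_name=n.lower())
        if n in module:
            a.is_kinase = True
            a.go_terms = set(target_terms) | {str(rng.choice(DECOY_TERMS))}
        else:
            a.is_kinase = bool(rng.random() < frac_kinase)
            a.is_phosphatase = (not a.is_kinase) and bool(rng.random() < 0.01)
            n_terms = int(rng.integers(1, 4))
            a.go_terms = set(
                str(t) for t in rng.choice(DECOY_TERMS, size=n_terms, replace=False)
            )
        if n in folds:
            a.phospho_fold_change = folds[n]
        attrs.set(n, a)
    return attrs


def plant_scenario(
    g: Interactome,
    n_probes: int = 20,
    distance_law: dict[int, float] | None = None,
    module_size: int = 14,
    frac_kinase: float = 0.05,
    rng_seed: int = 0,
    seed_name: str = "SEED",
) -> DiseaseScenario:
    """Plant one disease scenario into a copy of the background graph.

    Adds the seed, the kinase-module clique with adapters, and a probe
    set at distances drawn from ``distance_law`` (achieved geodesic
    distances are recorded in ``truth['planted_distances']``).
    """
    law = dict(distance_law or DEFAULT_DISTANCE_LAW)
    rng = np.random.default_rng(rng_seed)
    work = g.copy()
    core = _plant_core(work, module_size, rng)
    folds, distances = _attach_condition(work, core, seed_name, n_probes, law, rng)
    attrs = _annotate(work, core, folds, frac_kinase, rng)
    return DiseaseScenario(
        interactome=work,
        seed_node=seed_name,
        probe_set=folds,
        attrs=attrs,
        truth={
            "planted_module": set(core.module),
            "planted_distances": distances,
            "adapters": list(core.adapters),
            "target_terms": list(TARGET_TERMS),
            "rng_seed": rng_seed,
        },
    )


def paired_scenarios(
    n: int = 500,
    model: str = "preferential_attachment",
    params: dict | None = None,
    n_probes: int = 20,
    distance_law: dict[int, float] | None = None,
    module_size: int = 14,
    frac_kinase: float = 0.05,
    rng_seed: int = 0,
) -> tuple[DiseaseScenario, DiseaseScenario]:
    """Two conditions sharing one interactome and one planted module.

    This mirrors the two-disease design: distinct seed proteins
    (``SEED_A``, ``SEED_B``), disjointly sampled probe sets, but a common
    underlying kinase module that the combined analysis should isolate.
    Both scenarios reference the same :class:`Interactome` object, which
    contains both seeds.
    """
    law = dict(distance_law or DEFAULT_DISTANCE_LAW)
    rng = np.random.default_rng(rng_seed)
    g = generate_interactome(n, model=model, params=params,
                             rng_seed=int(rng.integers(0, 2**31 - 1)))
    core = _plant_core(g, module_size, rng)
    scenarios = []
    other_seeds = {"SEED_A", "SEED_B"}
    for seed_name in ("SEED_A", "SEED_B"):
        folds, distances = _attach_condition(
            g, core, seed_name, n_probes, law, rng,
            exclude=other_seeds - {seed_name},
        )
        scenarios.append((seed_name, folds, distances))
    # annotate once on the final shared graph, then give each condition
    # its own table carrying only its probes' fold-changes
    out = []
    for seed_name, folds, distances in scenarios:
        attrs = _annotate(g, core, folds, frac_kinase,
                          np.random.default_rng(rng_seed + 101))
        out.append(
            DiseaseScenario(
                interactome=g,
                seed_node=seed_name,
                probe_set=folds,
                attrs=attrs,
                truth={
                    "planted_module": set(core.module),
                    "planted_distances": distances,
                    "adapters": list(core.adapters),
                    "target_terms": list(TARGET_TERMS),
                    "rng_seed": rng_seed,
                },
            )
        )
    return out[0], out[1]


def write_scenario(sc: DiseaseScenario, outdir: str | Path) -> None:
    """Emit G.sif, attrs.tsv, probes.txt and truth.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "G.sif").write_text(sif_string(sc.interactome))
    with open(outdir / "attrs.tsv", "w") as fh:
        write_attributes(sc.attrs, fh)
    with open(outdir / "probes.txt", "w") as fh:
        for p in sorted(sc.probe_set):
            fh.write(f"{p}\t{sc.probe_set[p]:+.3f}\n")
    truth = dict(sc.truth)
    truth["planted_module"] = sorted(truth["planted_module"])
    truth["seed_node"] = sc.seed_node
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
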