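# Methods

`acanthonet` implements a topological analysis that asks how a disease
protein without catalytic activity (the *seed*; in neuroacanthocytosis,
the membrane transporter Xk or the cytosolic protein chorein) can shape a
cell's tyrosine phosphoproteome through the protein–protein interaction
network. The observable is a *probe set*: proteins whose phosphorylation
changes by at least twofold between patients and controls. The analysis
is purely graph-theoretic; all biochemistry enters through node
annotations.

## The network model

The interactome is an undirected simple graph *G = (N, E)* over
normalized protein symbols. Curated interaction records may be directed
("state change", optionally activation/inhibition) or undirected
("complex formation"); this direction and effect information is retained
as edge metadata but deliberately ignored by every topological
computation, because geodesic structure is defined on the undirected
graph. Assembly applies three cleaning rules: lexical identifier
normalization (trim, uppercase, optional alias map — no remote symbol
service, keeping the package fully offline), collapse of duplicate and
reciprocal records onto one undirected edge (first record's metadata
wins), and removal of self-loops, which would otherwise distort
centrality scores.

## Stage A — seed-to-probe sub-networks

All shortest paths from the seed are computed with a breadth-first
variant of Dijkstra's algorithm in which the single predecessor per node
is replaced by a *predecessor set*: p ∈ preds(n) iff p immediately
precedes n on at least one geodesic from the source. The predecessor
sets form a DAG; the geodesic count satisfies σ(n) = Σ_{p∈preds(n)} σ(p),
and individual paths are reconstructed by a forward walk over the DAG in
lexicographic order. Because the DAG can encode exponentially many
paths, enumeration takes a cap (default 10,000) and reports truncation
explicitly. BFS rather than a priority queue is used because the graphs
are unweighted, giving identical results at lower complexity; a weighted
Dijkstra traversal is kept behind the same contract.

The condition's sub-network (`probe_network`) is the union of all
seed→probe geodesics — nodes and edges on at least one shortest path.
An `induced` mode (all interactome edges among the same nodes) is
provided as well; path-union is the default because the object of
interest is the shortest-path structure itself. Whether probe↔probe
geodesics should also be included is genuinely open; they are not,
keeping the network a star of geodesic bundles rooted at the seed.

## Centrality indexes

Seven per-node indexes are computed (n nodes, d geodesic distance,
Δ component diameter):

| index | definition | convention |
|---|---|---|
| degree | neighbor count | |
| eccentricity | 1 / max_w d(v,w) | reciprocal: higher = central |
| closeness | 1 / Σ_w d(v,w) | reciprocal |
| radiality | Σ_{w≠v} (Δ+1−d(v,w)) / (n−1) | |
| stress | Σ_{s<t} σ_st(v) | unordered pairs, endpoints excluded |
| betweenness | Σ_{s<t} σ_st(v)/σ_st | unordered pairs |
| centroid | min_{w≠v} [γ_v(w) − γ_w(v)] | γ_v(w) = #{u : d(u,v) < d(u,w)} |

Notes on deliberate choices:

* Pair summation is over unordered pairs (s < t). Implementations in
  the wild differ by a factor of two here; every ratio-to-average output
  is invariant to the choice, which is why downstream filters are
  expressed as ratios and above-mean comparisons.
* In γ, nodes equidistant from v and w count for neither side, making
  f(v,w) = γ_v(w) − γ_w(v) antisymmetric; on a vertex-transitive graph
  every centroid value is 0.
* Δ is taken as the maximum geodesic distance within the component —
  the natural reading where radiality is shift-positive.
* Disconnected inputs are scored per component with a warning;
  cross-component pairs are excluded rather than treated as infinite.
  A single-node component has its reciprocal indexes reported as 0 and
  the node recorded in a `degenerate` set.
* Betweenness/stress use Brandes-style single-source accumulation
  (O(n·m)); centroid uses the all-pairs distance matrix (scipy csgraph
  BFS) with a vectorized γ comparison, O(n³) in numpy, fine for the
  few-hundred-node networks this pipeline produces.
* "Top" reporting (ratios, scatter flags) breaks ties lexicographically.

Network-level statistics: average geodesic length over unordered
reachable pairs, mean local clustering (degree < 2 contributes 0), mean
over nodes of the mean neighbor degree, and density. Values are reported
at full precision; an `integer_rounded` report mode exists because
coarse summaries of near-clique modules are conventionally printed as
integers (a 14-node module with 89 of 91 edges rounds to average path 1,
clustering 1).

## Stage B — shared-module extraction

For each of two conditions: the stage-A geodesic network is unioned
with the first-neighbor expansion of that condition's *probe set* (the
induced subgraph on probes plus all their direct interactors — the
expansion is of the probes, not of the whole geodesic network, because
the kinases acting on the phosphoproteome are by definition probe
neighbors). The two "enriched" networks are then intersected
*edge-wise*: an interaction survives only if present in both, and the
node set is the endpoints of surviving edges. The largest connected
component is kept (the pipeline default; empirically the shared
signaling space forms one dominant component). Then two filters:

1. **Dual-centrality filter** — keep nodes with *both* centroid and
   betweenness strictly above the network mean (strict inequality, so a
   perfectly symmetric network correctly yields nothing).
2. **GO filter** — keep nodes annotated to at least one of the target
   categories ("erythrocyte development", "neurogenesis" by default).
   Matching is literal and case-folded against the supplied annotation
   strings; no ontology descendant closure is attempted, because the
   annotation layer is a flattened label table. An enrichment-ranked
   alternative is available through the `enrichment` function
   (hypergeometric upper-tail test with Benjamini–Hochberg correction),
   but plain membership is the default interpretation.

A manifest records node/edge counts after every step; counts are
non-increasing along intersect → centrality filter → GO filter.

## The synthetic generator

Background graphs: Barabási–Albert preferential attachment with m = 5
(matching the ≈5 interactions per protein of curated mammalian
interactomes and their heavy-tailed degrees), with duplication–divergence
and Erdős–Rényi alternatives.

A planted scenario adds, to one background graph:

* a **module**: the `module_size` (default 14) highest-degree background
  nodes, completed into a clique, each given a private low-degree
  "adapter" interactor. Planting the module on hubs is a deliberate
  design choice: in real interactomes the signaling kinases recovered by
  this kind of analysis *are* among the best-connected proteins, and the
  centrality filter is only meaningful when the module carries genuine
  shared traffic. Module nodes are kinase-flagged and carry both target
  GO categories; no background node ever does.
* per condition, a **seed** adjacent to every module node, and a probe
  set of background proteins at geodesic distances drawn from a law
  (default 40% at 2, 45% at 3, 15% at 4). Distance-2 probes are wired as
  substrates of module kinases, round-robin so every kinase acts on at
  least one probe per condition; distance-3 probes attach to adapters
  (round-robin over adapters); farther probes are selected among nodes
  already at the drawn distance, with bounded redraws from the law when
  a distance is unachievable (an error listing achievable distances
  fires only if the law itself is unsatisfiable). Achieved distances are
  re-measured on the final graph and recorded as truth.
* signed fold-changes for probes: log-normal magnitude (µ = 1, σ = 0.3
  on the log scale) resampled to stay ≥ 2, random sign — spanning the
  2–4.5 range typical of densitometric phospho screens.
* background annotation noise: kinase flags at `frac_kinase`
  (default 0.05, roughly double the genomic kinome fraction, as
  interaction databases over-represent signaling proteins), phosphatase
  flags at 0.01, and one to three decoy GO labels per node.

Paired scenarios share the background, module and adapters but have
distinct seeds and independently sampled probe sets — the two-disease
design. The construction makes exact module recovery a provable
tendency rather than an accident: clique edges enter both enriched
networks through the probes' first-neighbor expansions (every module
kinase neighbors a probe in each condition), adapter pendants enter both
geodesic networks (every adapter relays a distance-3 probe) and
guarantee every module node a betweenness floor in the intersection,
and the GO filter is exactly satisfied by the module. Measured at the
defaults (n = 500 background nodes, 20 probes per condition, module 14),
the full pipeline returns exactly the planted module in 10/10 seeded
runs; problem sizes were chosen so the whole acceptance run completes in
seconds.

What the generator does **not** emulate: correlated annotation noise
(real GO labels cluster on network neighborhoods), probe sets that
overlap between conditions, false-positive/negative interactions,
multi-component interactomes with large isolated fractions, and any
quantitative realism in fold-change values. Passing the recovery test
therefore shows the pipeline's logic is sound under its own assumptions,
not that real phosphoproteomic data will yield so clean a module.

## Numerical and degenerate-input conventions

* All iteration orders (neighbors, components, output rows, SIF lines)
  are lexicographic; identical inputs give byte-identical outputs, and
  all randomness flows from a single integer seed per scenario.
* Stress and centroid are exact integers; betweenness is float with the
  only rounding coming from the σ ratios.
* Empty intersections warn and return an empty graph at the library
  level; the pipeline aborts with the step name, since continuing is
  meaningless.
* Duplicate attribute rows: last wins, with a warning (tables aggregated
  from several databases plausibly conflict).
* Hypergeometric p-values come from `scipy.stats.hypergeom.sf`, BH
  q-values from `scipy.stats.false_discovery_control`.

## Known limitations

* The centroid computation holds an n×n distance matrix; fine to a few
  thousand nodes, not meant for full 30k-node interactomes (stage A
  reduces the graph before any centrality is computed).
* Only unweighted geodesics drive the pipeline; the weighted traversal
  exists but no weighted centralities are offered.
* No GO ontology reasoning: a node annotated only to a descendant of a
  target category is not matched.
* First-neighbor "enrichment" composes the probe expansion with the
  geodesic network; alternative compositions (expanding the seed's own
  neighborhood as well) are not explored.
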