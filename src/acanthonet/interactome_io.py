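"""Interactome data model and text I/O.

The analyses in this package operate on a protein--protein interaction
network treated as an undirected simple graph G = (N, E): nodes are
normalized protein symbols, edges are unordered pairs with optional
biochemical metadata (interaction kind, directionality, effect,
provenance).  Direction and effect are *metadata only* -- every
topological computation ignores them.

Supported text formats:

* Cytoscape SIF ("A rel B [C ...]"; a single token makes an isolated
  node), TAB- or whitespace-delimited.
* Two-column edge-list TSV.
* TAB-delimited node-attribute tables with a header row (Cytoscape-style),
  carrying approved names, kinase/phosphatase flags, signed phospho
  fold-changes and GO category labels.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx

logger = logging.getLogger("acanthonet")

EDGE_KINDS = ("state_change", "complex_formation", "unspecified")
EFFECTS = ("activation", "inhibition", "none")

#: default relation token written when an edge carries no kind metadata
DEFAULT_RELATION = "pp"

# tokens (case-insensitive) accepted as True in boolean attribute columns
DEFAULT_TRUE_TOKENS = frozenset({"yes", "y", "true", "1", "t", "kinase", "phosphatase"})


class SIFParseError(ValueError):
    """Raised on a malformed SIF line (reports the 1-based line number)."""


class SchemaError(KeyError):
    """Raised when a mapped attribute column is missing from the header."""


@dataclass
class InteractionRecord:
    """One binary interaction as curated in a source database.

    ``kind`` distinguishes directed biochemical "state change" records
    from undirected "complex formation" records; ``effect`` optionally
    refines a state change as activation or inhibition.
    """

    source_id: str
    target_id: str
    kind: str = "unspecified"
    directed: bool = False
    effect: str = "none"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown interaction kind: {self.kind!r}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect: {self.effect!r}")
        if self.kind == "complex_formation" and self.directed:
            raise ValueError("complex_formation interactions are undirected")


class Interactome:
    """Undirected simple graph of protein symbols.

    Invariants (checked by :func:`validate`): no self-loops, no duplicate
    edges, every edge endpoint is a node.  Isolated nodes are allowed.
    Edge metadata (an :class:`InteractionRecord` summary dict) lives in
    the underlying :class:`networkx.Graph` edge attributes.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph: nx.Graph = graph if graph is not None else nx.Graph()

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def edge_meta(self, a: str, b: str) -> dict:
        return dict(self.graph.edges[a, b])

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_node(self, n: str) -> bool:
        return self.graph.has_node(n)

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def neighbors(self, n: str) -> set[str]:
        return set(self.graph.neighbors(n))

    def degree(self, n: str) -> int:
        return self.graph.degree(n)

    def copy(self) -> "Interactome":
        return Interactome(self.graph.copy())

    def __len__(self) -> int:
        return self.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<Interactome {self.number_of_nodes()} nodes, "
            f"{self.number_of_edges()} edges>"
        )

    # -- mutation (cleaning enforced at insertion) -----------------------
    def add_node(self, n: str) -> None:
        self.graph.add_node(n)

    def add_edge(self, a: str, b: str, **meta) -> None:
        if a == b:
            return  # self-loops are never representable
        if self.graph.has_edge(a, b):
            return  # first-wins: keep existing metadata
        self.graph.add_edge(a, b, **meta)

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "Interactome":
        """Wrap a networkx graph, dropping self-loops."""
        g = nx.Graph(graph)  # collapses duplicates/multi-edges
        g.remove_edges_from(nx.selfloop_edges(g))
        return cls(g)


def validate(g: Interactome) -> None:
    """Assert the Interactome invariants; raises AssertionError on breach."""
    assert not isinstance(g.graph, (nx.DiGraph, nx.MultiGraph)), "graph must be simple undirected"
    for a, b in g.graph.edges:
        assert a != b, f"self-loop on {a!r}"
        assert g.graph.has_node(a) and g.graph.has_node(b)
    for n in g.graph.nodes:
        assert isinstance(n, str) and n, f"invalid node id {n!r}"


# ---------------------------------------------------------------------------
# SIF / edge-list readers and writers
# ---------------------------------------------------------------------------

def _split_line(line: str, dialect: str) -> list[str]:
    if dialect == "tab" or (dialect == "auto" and "\t" in line):
        return [tok.strip() for tok in line.split("\t") if tok.strip()]
    return line.split()


def read_sif(stream: TextIO | str, dialect: str = "auto") -> Interactome:
    """Parse Cytoscape SIF text into a cleaned :class:`Interactome`.

    Lines are ``"A"`` (isolated node), or ``"A rel B [C ...]"`` which
    fans out to edges A-B, A-C, ...  Self-loops are dropped and duplicate
    edges merged.  A two-token line is malformed SIF.
    """
    if dialect not in ("tab", "whitespace", "auto"):
        raise ValueError(f"unknown SIF dialect: {dialect!r}")
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    g = Interactome()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        tokens = _split_line(line, dialect)
        if len(tokens) == 1:
            g.add_node(tokens[0])
        elif len(tokens) == 2:
            raise SIFParseError(
                f"line {lineno}: 2 tokens is not valid SIF "
                f"(expected 'A', or 'A rel B [C ...]'): {line!r}"
            )
        else:
            src, rel = tokens[0], tokens[1]
            for tgt in tokens[2:]:
                g.add_node(src)
                g.add_node(tgt)
                g.add_edge(src, tgt, relation=rel)
    return g


def write_sif(g: Interactome, stream: TextIO) -> None:
    """Emit SIF text; ``read_sif(write_sif(g))`` reproduces g exactly.

    One line per edge plus one single-token line per isolated node;
    output is sorted, hence byte-deterministic for a given graph.
    """
    for a, b in sorted(tuple(sorted(e)) for e in g.graph.edges):
        rel = g.graph.edges[a, b].get("relation", DEFAULT_RELATION)
        stream.write(f"{a}\t{rel}\t{b}\n")
    for n in sorted(g.graph.nodes):
        if g.graph.degree(n) == 0:
            stream.write(f"{n}\n")


def sif_string(g: Interactome) -> str:
    """Convenience: :func:`write_sif` into a string."""
    buf = io.StringIO()
    write_sif(g, buf)
    return buf.getvalue()


def read_edgelist(stream: TextIO | str) -> Interactome:
    """Read a two-column (TSV or whitespace) edge list."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    g = Interactome()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = _split_line(line, "auto")
        if len(tokens) != 2:
            raise SIFParseError(f"line {lineno}: expected 2 columns, got {len(tokens)}")
        g.add_node(tokens[0])
        g.add_node(tokens[1])
        g.add_edge(tokens[0], tokens[1])
    return g


def read_network(stream: TextIO | str) -> Interactome:
    """Sniff SIF vs two-column edge list and parse accordingly.

    If every multi-token line has exactly two tokens the file is taken
    as an edge list; otherwise it is parsed as SIF.
    """
    if not isinstance(stream, str):
        stream = stream.read()
    widths = {
        len(_split_line(line, "auto"))
        for line in stream.splitlines()
        if line.strip()
    }
    if widths and widths <= {2}:
        return read_edgelist(stream)
    return read_sif(stream)


# ---------------------------------------------------------------------------
# Node attribute tables
# ---------------------------------------------------------------------------

@dataclass
class NodeAttributes:
    approved_name: str = ""
    aliases: set = field(default_factory=set)
    is_kinase: bool = False
    is_phosphatase: bool = False
    phospho_fold_change: float | None = None
    go_terms: set = field(default_factory=set)
    extra: dict = field(default_factory=dict)


class NodeAttributeTable:
    """Per-protein annotation layer keyed by node symbol."""

    def __init__(self, records: dict[str, NodeAttributes] | None = None):
        self._records: dict[str, NodeAttributes] = dict(records or {})

    def __contains__(self, node: str) -> bool:
        return node in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def get(self, node: str) -> NodeAttributes:
        return self._records.get(node, NodeAttributes())

    def set(self, node: str, attrs: NodeAttributes) -> None:
        self._records[node] = attrs

    def kinases(self) -> set[str]:
        return {n for n, a in self._records.items() if a.is_kinase}

    def phosphatases(self) -> set[str]:
        return {n for n, a in self._records.items() if a.is_phosphatase}

    def fold_changes(self) -> dict[str, float]:
        return {
            n: a.phospho_fold_change
            for n, a in self._records.items()
            if a.phospho_fold_change is not None
        }

    def term_map(self) -> dict[str, set[str]]:
        """Invert annotations into term -> node-set (for enrichment)."""
        out: dict[str, set[str]] = {}
        for n, a in self._records.items():
            for t in a.go_terms:
                out.setdefault(t.casefold(), set()).add(n)
        return out

    def items(self):
        return self._records.items()


#: canonical schema keys understood by :func:`read_attributes`
SCHEMA_KEYS = (
    "id", "approved_name", "aliases", "is_kinase", "is_phosphatase",
    "fold_change", "go_terms",
)

DEFAULT_SCHEMA = {
    "id": "id",
    "approved_name": "approved_name",
    "aliases": "aliases",
    "is_kinase": "is_kinase",
    "is_phosphatase": "is_phosphatase",
    "fold_change": "fold_change",
    "go_terms": "go_terms",
}


def _parse_bool(token: str, true_tokens: frozenset) -> bool:
    return token.strip().casefold() in true_tokens


def read_attributes(
    stream: TextIO | str,
    schema: Mapping[str, str] | None = None,
    true_tokens: Iterable[str] = DEFAULT_TRUE_TOKENS,
    list_sep: str = ";",
) -> NodeAttributeTable:
    """Parse a TAB-delimited node attribute table (header row required).

    ``schema`` maps canonical keys (``id``, ``approved_name``, ``aliases``,
    ``is_kinase``, ``is_phosphatase``, ``fold_change``, ``go_terms``) to
    the file's column names; only ``id`` is mandatory, other keys may be
    omitted.  Multi-valued cells (aliases, GO terms) are split on
    ``list_sep``.  Duplicate rows for a node: last wins, with a warning.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    explicit = schema is not None
    schema = dict(schema) if explicit else dict(DEFAULT_SCHEMA)
    true_tokens = frozenset(t.casefold() for t in true_tokens)

    header_line = stream.readline().rstrip("\n")
    if not header_line.strip():
        return NodeAttributeTable()
    header = [h.strip() for h in header_line.split("\t")]
    col_index: dict[str, int] = {}
    for key, colname in schema.items():
        if key not in SCHEMA_KEYS:
            raise SchemaError(f"unknown schema key {key!r}")
        if colname is None:
            continue
        if colname not in header:
            # an explicitly mapped column must exist; with the default
            # schema only the id column is mandatory
            if key == "id" or explicit:
                raise SchemaError(f"mapped column {colname!r} missing from header {header}")
            continue
        col_index[key] = header.index(colname)

    if "id" not in col_index:
        raise SchemaError(f"id column {schema.get('id')!r} missing from header {header}")

    records: dict[str, NodeAttributes] = {}
    for lineno, raw in enumerate(stream, start=2):
        if not raw.strip():
            continue
        cells = raw.rstrip("\n").split("\t")

        def cell(key: str) -> str:
            i = col_index.get(key)
            if i is None or i >= len(cells):
                return ""
            return cells[i].strip()

        node = cell("id")
        if not node:
            continue
        if node in records:
            logger.warning("duplicate attribute row for %r at line %d: last wins", node, lineno)
        fc_text = cell("fold_change")
        fold: float | None = None
        if fc_text not in ("", "-", "NA", "na", "NaN"):
            try:
                fold = float(fc_text.replace("+", "", 1))
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: non-numeric fold-change {fc_text!r}"
                ) from exc
        records[node] = NodeAttributes(
            approved_name=cell("approved_name"),
            aliases={a for a in cell("aliases").split(list_sep) if a},
            is_kinase=_parse_bool(cell("is_kinase"), true_tokens),
            is_phosphatase=_parse_bool(cell("is_phosphatase"), true_tokens),
            phospho_fold_change=fold,
            go_terms={t.strip() for t in cell("go_terms").split(list_sep) if t.strip()},
        )
    return NodeAttributeTable(records)


def write_attributes(attrs: NodeAttributeTable, stream: TextIO, list_sep: str = ";") -> None:
    """Write the table in the canonical TAB-delimited layout."""
    stream.write("\t".join(DEFAULT_SCHEMA[k] for k in SCHEMA_KEYS) + "\n")
    for node in sorted(attrs):
        a = attrs.get(node)
        fold = "" if a.phospho_fold_change is None else f"{a.phospho_fold_change:+g}"
        stream.write(
            "\t".join(
                [
                    node,
                    a.approved_name,
                    list_sep.join(sorted(a.aliases)),
                    "yes" if a.is_kinase else "no",
                    "yes" if a.is_phosphatase else "no",
                    fold,
                    list_sep.join(sorted(a.go_terms)),
                ]
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# Normalization / assembly
# ---------------------------------------------------------------------------

def normalize_symbol(symbol: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Lexical identifier normalization: trim, uppercase, alias substitution."""
    s = symbol.strip().upper()
    if alias_map:
        s = alias_map.get(s, s)
    return s


def normalize_merge(
    records: Iterable[InteractionRecord],
    alias_map: Mapping[str, str] | None = None,
) -> Interactome:
    """Assemble a cleaned undirected graph from raw interaction records.

    Identifiers are normalized lexically; A->B and B->A collapse onto one
    undirected edge; records whose endpoints normalize to the same symbol
    become self-loops and are dropped (counted, not an error).  Directed /
    effect metadata of the first record seen for a pair is retained in
    ``edge_meta`` but plays no role in topology.
    """
    g = Interactome()
    dropped_self_loops = 0
    merged_duplicates = 0
    for rec in records:
        a = normalize_symbol(rec.source_id, alias_map)
        b = normalize_symbol(rec.target_id, alias_map)
        if not a or not b:
            raise ValueError(f"empty identifier after normalization in {rec!r}")
        g.add_node(a)
        if a == b:
            dropped_self_loops += 1
            continue
        g.add_node(b)
        if g.has_edge(a, b):
            merged_duplicates += 1
            continue
        g.add_edge(
            a, b,
            kind=rec.kind, directed=rec.directed,
            effect=rec.effect, provenance=rec.provenance,
        )
    g.graph.graph["dropped_self_loops"] = dropped_self_loops
    g.graph.graph["merged_duplicates"] = merged_duplicates
    return g


def connected_components(g: Interactome) -> list[set[str]]:
    """Connected components, largest first; ties by lexicographic min node."""
    comps = [set(c) for c in nx.connected_components(g.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps
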