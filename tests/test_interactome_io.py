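"""SIF/attribute parsing, normalization, and component extraction."""

import io
import random

import pytest

from acanthonet import (
    InteractionRecord,
    SchemaError,
    SIFParseError,
    connected_components,
    normalize_merge,
    read_attributes,
    read_edgelist,
    read_network,
    read_sif,
    sif_string,
    validate,
)
from acanthonet.synthetic_data import generate_interactome

from .conftest import graph_from_edges


class TestReadSif:
    @pytest.mark.parametrize(
        "text,n_nodes,n_edges",
        [
            ("A pp B\n", 2, 1),
            ("A pp A\n", 1, 0),  # self-loop dropped, node kept
            ("A pp B\nB pp A\nA pp B\n", 2, 1),  # duplicates merged
            ("A pp B C D\n", 4, 3),  # fan-out expands
            ("LONER\n", 1, 0),
            ("", 0, 0),
            ("A\tpp\tB\n", 2, 1),  # TAB dialect auto-detected
        ],
    )
    def test_parsing(self, text, n_nodes, n_edges):
        g = read_sif(text)
        assert g.number_of_nodes() == n_nodes
        assert g.number_of_edges() == n_edges
        validate(g)

    def test_two_token_line_is_malformed(self):
        with pytest.raises(SIFParseError, match="line 2"):
            read_sif("A pp B\nA B\n")

    def test_network_sniffer_accepts_two_column_edge_list(self):
        g = read_network("A\tB\nB\tC\n")
        assert g.edges == {frozenset("AB"), frozenset("BC")}
        g2 = read_network("A pp B\nC\n")
        assert g2.number_of_nodes() == 3

    def test_edgelist_rejects_three_columns(self):
        with pytest.raises(SIFParseError):
            read_edgelist("A\tpp\tB\n")


class TestRoundTrip:
    def test_empty_graph_writes_empty(self):
        assert sif_string(graph_from_edges([])) == ""

    def test_round_trip_random_graphs(self, rng):
        for seed in range(5):
            g = generate_interactome(50, "erdos_renyi", {"p": 0.08},
                                     rng_seed=seed)
            back = read_sif(sif_string(g))
            assert back.nodes == g.nodes
            assert back.edges == g.edges

    def test_round_trip_preserves_isolated_nodes(self):
        g = graph_from_edges([("A", "B")], extra_nodes=["Z"])
        back = read_sif(sif_string(g))
        assert back.nodes == {"A", "B", "Z"}

    def test_deterministic_output(self):
        g = generate_interactome(30, "erdos_renyi", {"p": 0.2}, rng_seed=3)
        assert sif_string(g) == sif_string(g.copy())


class TestNormalizeMerge:
    def test_directed_pair_collapses(self):
        recs = [
            InteractionRecord("A", "B", kind="state_change", directed=True),
            InteractionRecord("B", "A", kind="state_change", directed=True),
            InteractionRecord("a ", "b", kind="complex_formation"),
        ]
        g = normalize_merge(recs)
        assert g.nodes == {"A", "B"}
        assert g.number_of_edges() == 1
        assert g.edge_meta("A", "B")["kind"] == "state_change"  # first wins

    def test_self_loop_dropped_and_counted(self):
        g = normalize_merge([InteractionRecord("A", "a")])
        assert g.nodes == {"A"}
        assert g.number_of_edges() == 0
        assert g.graph.graph["dropped_self_loops"] == 1

    def test_alias_substitution(self):
        g = normalize_merge(
            [InteractionRecord("FYN-ALIAS", "ABL1")],
            alias_map={"FYN-ALIAS": "FYN"},
        )
        assert g.nodes == {"FYN", "ABL1"}

    def test_complex_formation_cannot_be_directed(self):
        with pytest.raises(ValueError):
            InteractionRecord("A", "B", kind="complex_formation", directed=True)

    def test_edge_count_matches_set_oracle(self, rng):
        """1000 noisy records: edge count equals unique unordered pairs."""
        names = [f"P{i}" for i in range(60)]
        recs = []
        for _ in range(1000):
            a = rng.choice(names)
            b = a if rng.random() < 0.05 else rng.choice(names)
            if rng.random() < 0.3:
                a, b = f" {a.lower()}", b  # formatting noise
            recs.append(InteractionRecord(a, b))
        expected = {
            frozenset((r.source_id.strip().upper(), r.target_id.strip().upper()))
            for r in recs
        }
        expected = {e for e in expected if len(e) == 2}
        g = normalize_merge(recs)
        assert g.number_of_edges() == len(expected)
        validate(g)

    def test_idempotent(self):
        recs = [InteractionRecord("a", "B"), InteractionRecord("B", "C")]
        g1 = normalize_merge(recs)
        recs2 = [InteractionRecord(a, b) for a, b in
                 (tuple(sorted(e)) for e in g1.edges)]
        g2 = normalize_merge(recs2)
        assert g1.nodes == g2.nodes and g1.edges == g2.edges


ATTR_HEADER = "id\tapproved_name\taliases\tis_kinase\tis_phosphatase\tfold_change\tgo_terms\n"


class TestReadAttributes:
    def test_header_only_gives_empty_table(self):
        assert len(read_attributes(ATTR_HEADER)) == 0

    def test_basic_row(self):
        t = read_attributes(
            ATTR_HEADER + "FYN\tfyn kinase\tSLK;SYN\tyes\tno\t+2.84\terythrocyte development\n"
        )
        a = t.get("FYN")
        assert a.is_kinase and not a.is_phosphatase
        assert a.phospho_fold_change == pytest.approx(2.84)
        assert a.aliases == {"SLK", "SYN"}
        assert a.go_terms == {"erythrocyte development"}

    def test_duplicate_rows_last_wins(self, caplog):
        t = read_attributes(
            ATTR_HEADER + "FYN\t\t\tyes\tno\t\t\nFYN\t\t\tno\tno\t\t\n"
        )
        assert not t.get("FYN").is_kinase

    def test_missing_mapped_column_is_schema_error(self):
        with pytest.raises(SchemaError):
            read_attributes("id\tname\nFYN\tx\n", schema={"id": "id", "is_kinase": "kin"})

    def test_non_numeric_fold_change_reports_line(self):
        with pytest.raises(ValueError, match="line 2"):
            read_attributes(ATTR_HEADER + "FYN\t\t\tno\tno\ttwofold\t\n")

    def test_negative_fold_change(self):
        t = read_attributes(ATTR_HEADER + "ANXA4\t\t\tno\tno\t-2.4\t\n")
        assert t.get("ANXA4").phospho_fold_change == pytest.approx(-2.4)


class _UnionFind:
    def __init__(self, items):
        self.p = {x: x for x in items}

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def join(self, a, b):
        self.p[self.find(a)] = self.find(b)


class TestConnectedComponents:
    def test_path_is_one_component(self):
        g = graph_from_edges([("a", "b"), ("b", "c")])
        assert connected_components(g) == [{"a", "b", "c"}]

    def test_edgeless_nodes_are_singletons(self):
        g = graph_from_edges([], extra_nodes=["a", "b"])
        assert connected_components(g) == [{"a"}, {"b"}]

    def test_matches_union_find_oracle(self):
        for seed in range(10):
            g = generate_interactome(30, "erdos_renyi", {"p": 0.05}, rng_seed=seed)
            uf = _UnionFind(g.nodes)
            for e in g.edges:
                a, b = tuple(e)
                uf.join(a, b)
            roots = {}
            for n in g.nodes:
                roots.setdefault(uf.find(n), set()).add(n)
            comps = connected_components(g)
            assert sorted(map(sorted, comps)) == sorted(map(sorted, roots.values()))
            assert sum(len(c) for c in comps) == g.number_of_nodes()
            sizes = [len(c) for c in comps]
            assert sizes == sorted(sizes, reverse=True)
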