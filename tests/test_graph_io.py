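"""Edge-list/GMT/mapping IO, cleaning, and subnetwork operations."""

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetnet import (
    InteractionNetwork,
    LabelSet,
    IdMapping,
    apply_mapping,
    induce_subnetwork,
    largest_connected_component,
    load_gene_sets,
    load_mapping,
    load_network,
    write_network,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadNetwork:
    def test_tsv_cleaning_counts(self, tmp_path):
        """Self-loops and duplicate unordered pairs are dropped and counted."""
        p = _write(tmp_path, "net.tsv", "A\tB\nB\tA\nC\tC\nA\tB\n")
        net = load_network(p)
        assert net.nodes == {"A", "B", "C"}
        assert net.edges == {("A", "B")}
        assert net.cleaning.self_loops_dropped == 1
        assert net.cleaning.duplicate_edges_dropped == 2

    def test_sif_multi_target_expansion(self, tmp_path):
        p = _write(tmp_path, "net.sif", "A pp B C\n")
        net = load_network(p, dialect="sif")
        assert net.edges == {("A", "B"), ("A", "C")}

    def test_six_line_fixture_counts(self, tmp_path):
        """Hand-counted fixture: 5 distinct edges over 6 nodes (one repeat)."""
        text = "A\tB\nB\tC\nC\tD\nD\tE\nE\tF\nA\tB\n"
        net = load_network(_write(tmp_path, "f.tsv", text))
        assert net.n_edges == 5
        assert net.n_nodes == 6

    def test_malformed_record_names_line(self, tmp_path):
        p = _write(tmp_path, "bad.tsv", "A\tB\nA\tB\tC\n")
        with pytest.raises(ValueError, match=":2"):
            load_network(p)

    def test_empty_file_rejected(self, tmp_path):
        p = _write(tmp_path, "empty.tsv", "# only a comment\n")
        with pytest.raises(ValueError, match="no records"):
            load_network(p)

    def test_sif_isolated_node(self, tmp_path):
        p = _write(tmp_path, "iso.sif", "A pp B\nZ\n")
        net = load_network(p, dialect="sif")
        assert "Z" in net.nodes
        assert net.graph.degree("Z") == 0


class TestRoundTrip:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        edges=st.lists(
            st.tuples(st.integers(0, 12), st.integers(0, 12)), max_size=30
        ),
        isolated=st.sets(st.integers(13, 17), max_size=3),
    )
    def test_sif_round_trip(self, tmp_path_factory, edges, isolated):
        """write then load reproduces node and edge sets exactly."""
        net = InteractionNetwork.from_edges(
            ((f"n{u}", f"n{v}") for u, v in edges),
            nodes=(f"n{i}" for i in isolated),
        )
        p = tmp_path_factory.mktemp("rt") / "net.sif"
        write_network(net, p, dialect="sif")
        if net.n_nodes == 0:
            return  # an empty file is rejected by the loader
        back = load_network(p, dialect="sif")
        assert back.nodes == net.nodes
        assert back.edges == net.edges


class TestGeneSets:
    def test_dedup_within_record(self, tmp_path):
        p = _write(tmp_path, "g.gmt", "BBS\tna\tBBS1\tBBS2\tBBS1\n")
        labels = load_gene_sets(p)
        assert labels.disorders == {"BBS": frozenset({"BBS1", "BBS2"})}

    def test_shared_gene_union_semantics(self, tmp_path):
        p = _write(tmp_path, "g.gmt", "D1\tna\tG\tA\nD2\tna\tG\tB\n")
        labels = load_gene_sets(p)
        assert "G" in labels.disorders["D1"] and "G" in labels.disorders["D2"]
        assert sorted(labels.all_genes) == ["A", "B", "G"]

    def test_flat_count_with_many_disorders(self, tmp_path):
        """100 disorders, 674 distinct genes total: flat set size is 674."""
        lines = []
        gene_id = 0
        for d in range(100):
            n = 7 if d < 74 else 6  # 74*7 + 26*6 = 674
            genes = [f"g{gene_id + i}" for i in range(n)]
            gene_id += n
            lines.append("\t".join([f"D{d}", "na"] + genes))
        labels = load_gene_sets(_write(tmp_path, "big.gmt", "\n".join(lines) + "\n"))
        assert len(labels.disorders) == 100
        assert len(labels.all_genes) == 674

    def test_empty_record_names_set(self, tmp_path):
        p = _write(tmp_path, "g.gmt", "EMPTY\tna\n")
        with pytest.raises(ValueError, match="EMPTY"):
            load_gene_sets(p)


class TestApplyMapping:
    def test_merge_drops_self_loop(self):
        net = InteractionNetwork.from_edges([("g1", "g2")])
        labels = LabelSet(disorders={"D": frozenset({"g1"})})
        mapping = IdMapping(pairs={"g1": "P1", "g2": "P1"})
        mapped, _, report = apply_mapping(net, labels, mapping)
        assert mapped.nodes == {"P1"}
        assert mapped.n_edges == 0
        assert report.self_loops_from_merge == 1

    def test_identity_mapping_is_noop(self):
        net = InteractionNetwork.from_edges([("a", "b"), ("b", "c")])
        labels = LabelSet(disorders={"D": frozenset({"a", "c"})})
        mapped, mlabels, _ = apply_mapping(net, labels, IdMapping(pairs={}))
        assert mapped.nodes == net.nodes and mapped.edges == net.edges
        assert mlabels.disorders == labels.disorders

    def test_labels_absent_from_network_reported_and_dropped(self):
        net = InteractionNetwork.from_edges([("a", "b")])
        labels = LabelSet(disorders={"D": frozenset({"a", "zz", "yy"})})
        _, mlabels, report = apply_mapping(net, labels, IdMapping(pairs={}))
        assert report.labels_not_in_network == {"zz", "yy"}
        assert mlabels.all_genes == frozenset({"a"})

    def test_mapping_file_conflict_rejected(self, tmp_path):
        p = _write(tmp_path, "map.tsv", "a\tP1\na\tP2\n")
        with pytest.raises(ValueError, match="conflicting"):
            load_mapping(p)

    def test_mapping_file_unmapped_rows(self, tmp_path):
        p = _write(tmp_path, "map.tsv", "a\tP1\nb\t\n")
        m = load_mapping(p)
        assert m.pairs == {"a": "P1"} and m.unmapped == {"b"}


class TestComponentsAndInduction:
    def test_lcc_picks_largest(self):
        net = InteractionNetwork.from_edges(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("x", "y"), ("y", "z")]
        )
        assert largest_connected_component(net).nodes == {"a", "b", "c", "d", "e"}

    def test_lcc_of_connected_graph_is_itself(self, k4_pendant):
        assert largest_connected_component(k4_pendant).nodes == k4_pendant.nodes

    def test_lcc_tie_broken_by_smallest_member(self):
        """Components {4,4,2}: the tie between the two 4-cliques goes to the
        one containing the lexicographically smallest node."""
        g = nx.compose_all(
            [
                nx.complete_graph(["M", "N", "O", "P"]),
                nx.complete_graph(["A", "B", "C", "D"]),
                nx.Graph([("x", "y")]),
            ]
        )
        lcc = largest_connected_component(InteractionNetwork(graph=g))
        assert lcc.nodes == {"A", "B", "C", "D"}

    def test_lcc_idempotent(self, k5_k6_bridge):
        once = largest_connected_component(k5_k6_bridge)
        twice = largest_connected_component(once)
        assert twice.nodes == once.nodes and twice.edges == once.edges

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            largest_connected_component(InteractionNetwork(graph=nx.Graph()))

    @pytest.mark.parametrize(
        "genes, n_nodes, n_edges",
        [
            ({"q", "r"}, 0, 0),  # disjoint from the network
            ({"A", "B", "C"}, 3, 2),  # the whole path: identity
            ({"A", "C"}, 2, 0),  # non-adjacent endpoints of the path
        ],
    )
    def test_induce_on_path(self, path3, genes, n_nodes, n_edges):
        net, _ = path3
        sub = induce_subnetwork(net, genes)
        assert sub.n_nodes == n_nodes and sub.n_edges == n_edges

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_induce_idempotent_and_monotone(self, data):
        g = nx.gnp_random_graph(12, 0.3, seed=data.draw(st.integers(0, 100)))
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
        net = InteractionNetwork(graph=g)
        small = data.draw(st.sets(st.sampled_from(sorted(g.nodes)), max_size=8))
        extra = data.draw(st.sets(st.sampled_from(sorted(g.nodes)), max_size=4))
        sub = induce_subnetwork(net, small)
        again = induce_subnetwork(sub, small)
        assert again.nodes == sub.nodes and again.edges == sub.edges
        bigger = induce_subnetwork(net, small | extra)
        assert bigger.n_edges >= sub.n_edges
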