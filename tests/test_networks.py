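"""Similarity and disease networks: edge ranking, counting, serialization."""

import networkx as nx
import numpy as np
import pytest

import cskl
from cskl.exceptions import ParameterError


def pair(a, b, value, q, p=0.01):
    return cskl.PairResult(a, b, value, p_value=p, q_value=q)


FIVE_PAIRS = [
    pair("d1", "d2", 1.0, 0.001),
    pair("d2", "d3", 2.0, 0.002),
    pair("d3", "d4", 3.0, 0.010),
    pair("d4", "d5", 4.0, 0.020),
    pair("d1", "d5", 5.0, 0.040),
]


class TestDatasetNetwork:
    def test_top_edges_keeps_most_significant(self):
        net = cskl.build_dataset_network(FIVE_PAIRS, top_edges=3)
        assert net.number_of_edges() == 3
        assert set(net.edges) >= {("d1", "d2"), ("d2", "d3")}
        assert max(q for _, _, q in net.edges(data="q")) == 0.010

    def test_tie_break_falls_back_to_cskl_then_ids(self):
        tied = [
            pair("b1", "b2", 2.0, 0.01),
            pair("a1", "a2", 2.0, 0.01),
            pair("c1", "c2", 1.0, 0.01),
        ]
        net = cskl.build_dataset_network(tied, top_edges=2)
        assert set(map(frozenset, net.edges)) == {
            frozenset({"c1", "c2"}),
            frozenset({"a1", "a2"}),
        }

    def test_empty_input_gives_empty_network(self):
        net = cskl.build_dataset_network([])
        assert net.number_of_nodes() == 0 and net.number_of_edges() == 0

    def test_isolated_manifest_nodes_optional(self):
        net = cskl.build_dataset_network(
            FIVE_PAIRS[:1], manifest_ids=["d1", "d2", "dx"], include_isolated=True
        )
        assert "dx" in net.nodes and net.degree("dx") == 0

    def test_invalid_top_edges(self):
        with pytest.raises(ParameterError):
            cskl.build_dataset_network(FIVE_PAIRS, top_edges=0)

    def test_planted_communities_recovered(self, fitted_small, small_collection):
        _, labels, truth = small_collection
        net = fitted_small.to_network(q_threshold=0.05)
        for a, b in net.edges:
            assert labels[a] == labels[b]  # no cross-group edge at strict q
        planted = {tuple(sorted(p)) for p in zip(truth["id_a"], truth["id_b"])}
        assert {tuple(sorted(e)) for e in net.edges} == planted


class TestDiseaseNetwork:
    labels = {"d1": "A", "d2": "B", "d3": "A", "d4": "B", "d5": "A"}

    def test_weights_count_supporting_pairs(self):
        net = cskl.build_dataset_network(FIVE_PAIRS)
        disease = cskl.build_disease_network(net, self.labels)
        # cross-disease dataset edges: d1-d2, d2-d3, d3-d4, d4-d5 -> all A-B
        assert disease["A"]["B"]["weight"] == 4
        assert not disease.has_edge("A", "A")

    def test_within_disease_edges_vanish(self):
        net = cskl.build_dataset_network([pair("d1", "d3", 1.0, 0.01)])
        disease = cskl.build_disease_network(net, self.labels)
        assert disease.number_of_edges() == 0

    def test_min_weight_filters(self):
        net = cskl.build_dataset_network(FIVE_PAIRS)
        disease = cskl.build_disease_network(net, self.labels, min_weight=5)
        assert disease.number_of_edges() == 0

    def test_unlabeled_endpoints_dropped(self):
        net = cskl.build_dataset_network([pair("d1", "dx", 1.0, 0.01)])
        disease = cskl.build_disease_network(net, self.labels)
        assert disease.number_of_edges() == 0

    def test_min_weight_validation(self):
        with pytest.raises(ParameterError):
            cskl.build_disease_network(nx.Graph(), self.labels, min_weight=0)

    def test_weight_equals_recount_and_order_invariance(self, fitted_small, small_collection):
        _, labels, _ = small_collection
        significant = fitted_small.significant(0.05)
        net = cskl.build_dataset_network(significant)
        disease = cskl.build_disease_network(net, labels)
        for a, b, w in disease.edges(data="weight"):
            recount = sum(
                1
                for e in net.edges
                if {labels.get(e[0]), labels.get(e[1])} == {a, b}
            )
            assert w == recount
        reversed_net = cskl.build_dataset_network(significant[::-1])
        disease2 = cskl.build_disease_network(reversed_net, labels)
        assert nx.utils.graphs_equal(disease, disease2)

    def test_total_weight_bounded_by_cross_disease_edges(self):
        net = cskl.build_dataset_network(FIVE_PAIRS)
        disease = cskl.build_disease_network(net, self.labels, min_weight=1)
        cross = sum(
            1 for a, b in net.edges if self.labels[a] != self.labels[b]
        )
        total = sum(w for _, _, w in disease.edges(data="weight"))
        assert total == cross


class TestMergeNetworks:
    def build(self, edges):
        g = nx.Graph()
        for a, b, w in edges:
            g.add_edge(a, b, weight=w)
        return g

    def test_merge_with_empty_is_identity(self):
        net = self.build([("A", "B", 2)])
        merged = cskl.merge_networks([net, nx.Graph()])
        assert merged["A"]["B"]["weight"] == 2

    def test_weights_sum_across_platforms(self):
        merged = cskl.merge_networks(
            [self.build([("A", "B", 2)]), self.build([("A", "B", 3), ("B", "C", 1)])]
        )
        assert merged["A"]["B"]["weight"] == 5
        assert merged["B"]["C"]["weight"] == 1

    def test_commutative_and_associative(self):
        nets = [
            self.build([("A", "B", 1)]),
            self.build([("B", "C", 2)]),
            self.build([("A", "B", 4), ("C", "D", 1)]),
        ]
        forward = cskl.merge_networks(nets)
        backward = cskl.merge_networks(nets[::-1])
        nested = cskl.merge_networks([cskl.merge_networks(nets[:2]), nets[2]])
        assert nx.utils.graphs_equal(forward, backward)
        assert nx.utils.graphs_equal(forward, nested)


class TestExport:
    def test_graphml_roundtrip_preserves_attributes(self, tmp_path):
        net = cskl.build_dataset_network(FIVE_PAIRS, labels={"d1": "A", "d2": "B"})
        path = tmp_path / "net.graphml"
        cskl.export_network(net, path)
        back = cskl.import_network(path)
        assert nx.utils.graphs_equal(net, back)

    def test_empty_network_is_valid_graphml(self, tmp_path):
        path = tmp_path / "empty.graphml"
        cskl.export_network(nx.Graph(), path)
        assert cskl.import_network(path).number_of_nodes() == 0

    def test_tsv_sorted_by_descending_weight(self, tmp_path):
        import pandas as pd

        g = nx.Graph()
        g.add_edge("A", "B", weight=2)
        g.add_edge("B", "C", weight=7)
        g.add_edge("C", "D", weight=4)
        path = tmp_path / "edges.tsv"
        cskl.export_network(g, path, fmt="edge_list_tsv")
        frame = pd.read_csv(path, sep="\t")
        assert list(frame["weight"]) == [7, 4, 2]

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ParameterError):
            cskl.export_network(nx.Graph(), tmp_path / "x", fmt="dot")
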