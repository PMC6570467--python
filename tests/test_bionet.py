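"""Network construction: Tanimoto arithmetic, typed edges, the strict
similarity threshold, community labels and round-trip exports."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metaprior import build_network, detect_communities, export_graph, tanimoto
from metaprior.bionet import compounds_from_inputs
from metaprior.bionet_export import load_graphml
from metaprior.diffstat import DiffTable
from metaprior.synthio import CompoundRecord


def _bits(on, length=16):
    fp = np.zeros(length, dtype=np.uint8)
    fp[list(on)] = 1
    return fp


class TestTanimoto:
    def test_identity(self):
        a = _bits({1, 5, 9})
        assert tanimoto(a, a) == 1.0

    def test_disjoint(self):
        assert tanimoto(_bits({0, 1}), _bits({2, 3})) == 0.0

    def test_hand_enumeration(self):
        assert tanimoto(_bits({1, 2, 3}), _bits({2, 3, 4})) == pytest.approx(0.5)

    def test_all_zero_pair_is_zero(self):
        assert tanimoto(_bits(set()), _bits(set())) == 0.0

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            tanimoto(_bits({1}), _bits({1}, length=8))

    @settings(deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 15)), st.sets(st.integers(0, 15)))
    def test_symmetric_and_bounded(self, a, b):
        s = tanimoto(_bits(a), _bits(b))
        assert s == tanimoto(_bits(b), _bits(a))
        assert 0.0 <= s <= 1.0


def _diff_table(records):
    t = pd.DataFrame(records, columns=["feature", "raw_p", "fold_change",
                                       "direction"])
    t["test_name"], t["n_neg"], t["n_pos"] = "mwu", 5, 5
    return DiffTable("S00", "metabolite", t)


class TestBuildNetwork:
    def _two_compounds(self, sim_target):
        # intersection 7 bits; pad the union so |I|/|U| hits sim_target
        inter = set(range(7))
        union_size = int(round(7 / sim_target))
        extra = union_size - 7
        a = _bits(inter | set(range(7, 7 + (extra + 1) // 2)))
        b = _bits(inter | set(range(12, 12 + extra // 2)))
        return {"MA": CompoundRecord("MA", a), "MB": CompoundRecord("MB", b)}

    def test_exact_threshold_gets_no_edge(self):
        comps = self._two_compounds(0.7)
        assert tanimoto(comps["MA"].fingerprint,
                        comps["MB"].fingerprint) == pytest.approx(0.7)
        g = build_network(comps, {}, {}, [], threshold=0.7)
        assert g.number_of_edges() == 0

    def test_above_threshold_gets_weighted_edge(self):
        comps = self._two_compounds(0.875)
        g = build_network(comps, {}, {}, [], threshold=0.7)
        assert g.has_edge("MA", "MB")
        d = g.edges["MA", "MB"]
        assert d["edge_class"] == "chemical-similarity"
        assert d["weight"] > 0.7

    def test_shared_ec_links_gene_and_compound(self):
        comps = {"M1": CompoundRecord("M1", _bits({0}),
                                      ec_links={"1.1.1.14"})}
        g = build_network(comps, {"SORD": {"1.1.1.14"}}, {}, [],
                          threshold=0.7)
        assert g.edges["SORD", "1.1.1.14"]["edge_class"] == "gene-enzyme"
        assert g.edges["M1", "1.1.1.14"]["edge_class"] == "compound-enzyme"

    def test_rpair_edges_from_symmetric_pairs(self):
        comps = compounds_from_inputs(
            {"M1": _bits({0}), "M2": _bits({5})}, rpairs={("M1", "M2")})
        g = build_network(comps, {}, {}, [], threshold=0.7)
        assert g.edges["M1", "M2"]["edge_class"] == "rpair"

    def test_empty_compounds_leave_entity_enzyme_edges(self):
        g = build_network({}, {"G1": {"2.7.1.1"}}, {"P1": {"2.7.1.1"}}, [],
                          threshold=0.7)
        classes = {d["edge_class"] for _, _, d in g.edges(data=True)}
        assert classes == {"gene-enzyme", "protein-enzyme"}

    def test_node_attributes_come_from_diff_tables(self):
        diff = _diff_table([("M1", 0.01, 2.5, "up")])
        comps = {"M1": CompoundRecord("M1", _bits({0}))}
        g = build_network(comps, {}, {}, [diff], threshold=0.7)
        assert g.nodes["M1"]["fold_change"] == 2.5
        assert g.nodes["M1"]["direction"] == "up"

    def test_missing_diff_record_gets_neutral_attributes(self):
        comps = {"M9": CompoundRecord("M9", _bits({0}))}
        g = build_network(comps, {}, {}, [], threshold=0.7)
        assert g.nodes["M9"]["fold_change"] == 1.0
        assert g.nodes["M9"]["direction"] == "unchanged"

    def test_edge_count_non_increasing_in_threshold(self, rng):
        comps = {f"M{i}": CompoundRecord(f"M{i}",
                                         (rng.random(32) < 0.5).astype(np.uint8))
                 for i in range(15)}
        counts = [build_network(comps, {}, {}, [], threshold=t).number_of_edges()
                  for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_construction(self, small_annotations):
        ann = small_annotations
        g1 = build_network(ann.compounds, {}, {}, [], threshold=0.7)
        g2 = build_network(ann.compounds, {}, {}, [], threshold=0.7)
        assert list(g1.nodes) == list(g2.nodes)
        assert list(g1.edges) == list(g2.edges)


class TestCommunities:
    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
        labels = detect_communities(g)
        assert len(set(labels.values())) == 2

    def test_complete_graph_single_community(self):
        g = nx.relabel_nodes(nx.complete_graph(6),
                             {n: f"n{n}" for n in range(6)})
        assert len(set(detect_communities(g).values())) == 1

    def test_bridged_cliques_separated(self):
        a, b = nx.complete_graph(10), nx.complete_graph(10)
        g = nx.disjoint_union(a, b)
        g.add_edge(0, 10)
        g = nx.relabel_nodes(g, {n: f"n{n:02d}" for n in g.nodes})
        labels = detect_communities(g)
        left = {labels[f"n{i:02d}"] for i in range(10)}
        right = {labels[f"n{i:02d}"] for i in range(10, 20)}
        assert left.isdisjoint(right)
        assert len(left) == len(right) == 1

    def test_empty_graph(self):
        assert detect_communities(nx.Graph()) == {}

    def test_components_never_merged(self, small_annotations):
        g = build_network(small_annotations.compounds, {}, {}, [],
                          threshold=0.7)
        labels = detect_communities(g)
        components = list(nx.connected_components(g))
        for i, comp in enumerate(components):
            used = {labels[n] for n in comp}
            for other in components[i + 1:]:
                assert used.isdisjoint({labels[n] for n in other})


class TestExport:
    def _graph(self):
        diff = _diff_table([("M1", 0.01, 2.0, "up"), ("M2", 0.2, 0.5, "down")])
        comps = compounds_from_inputs(
            {"M1": _bits({0, 1, 2}), "M2": _bits({0, 1, 3})},
            rpairs={("M1", "M2")})
        return build_network(comps, {"G1": {"1.1.1.1"}}, {}, [diff],
                             threshold=0.7)

    def test_graphml_roundtrip(self, tmp_path):
        g = self._graph()
        path = tmp_path / "net.graphml"
        export_graph(g, path, fmt="graphml")
        back = load_graphml(path)
        assert set(back.nodes) == set(g.nodes)
        assert {frozenset(e) for e in back.edges} == \
            {frozenset(e) for e in g.edges}
        for n in g.nodes:
            assert back.nodes[n]["kind"] == g.nodes[n]["kind"]
            assert back.nodes[n]["fold_change"] == pytest.approx(
                g.nodes[n]["fold_change"])
        for u, v in g.edges:
            assert back.edges[u, v]["edge_class"] == g.edges[u, v]["edge_class"]

    def test_sif_line_count_equals_edges(self, tmp_path):
        g = self._graph()
        path = tmp_path / "net.sif"
        export_graph(g, path, fmt="sif")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == g.number_of_edges()

    def test_render_attributes_encode_fold_and_direction(self, tmp_path):
        g = self._graph()
        path = tmp_path / "net.graphml"
        export_graph(g, path, fmt="graphml")
        back = load_graphml(path)
        assert back.nodes["M1"]["color"] == "red"
        assert back.nodes["M2"]["color"] == "blue"
        # size grows with |log2 fold change|
        assert back.nodes["M1"]["size"] > back.nodes["G1"]["size"]

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_graph(self._graph(), tmp_path / "x", fmt="gexf")
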