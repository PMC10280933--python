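"""Triple assembly, degrees, hubs, subnetworks, core-gene intersection, I/O."""

import pandas as pd
import pytest

from cernascope.cerna import (CeRNANetwork, assemble_cerna, core_mrnas,
                              extract_subnetwork, hub_lncrnas, node_degrees,
                              read_sif, read_triples, write_sif, write_triples)


def pairs_frame(pairs):
    return pd.DataFrame(pairs, columns=["lncrna_id", "mrna_id"])


def interactions(rows, source_type, target_type):
    return pd.DataFrame(
        {"source_id": [r[0] for r in rows],
         "target_id": [r[1] for r in rows],
         "source_type": source_type, "target_type": target_type})


@pytest.fixture()
def small_net():
    # L1 pairs with G1 (miRNAs m1, m2) and G2 (m2); L2 pairs with G2 (m3)
    pairs = pairs_frame([("L1", "G1"), ("L1", "G2"), ("L2", "G2")])
    lnc_mir = interactions([("L1", "m1"), ("L1", "m2"), ("L2", "m3")],
                           "lncRNA", "miRNA")
    mir_mrna = interactions([("m1", "G1"), ("m2", "G1"), ("m2", "G2"),
                             ("m3", "G2")], "miRNA", "mRNA")
    return assemble_cerna(pairs, lnc_mir, mir_mrna)


class TestAssemble:
    def test_definition_forced_intersection(self):
        net = assemble_cerna(
            pairs_frame([("L1", "G1")]),
            interactions([("L1", "m1"), ("L1", "m2")], "lncRNA", "miRNA"),
            interactions([("m1", "G1"), ("m3", "G1")], "miRNA", "mRNA"))
        assert net.triples == frozenset({("L1", "m1", "G1")})
        assert net.n_edges == 2
        assert len(net.lncrna_nodes | net.mirna_nodes | net.mrna_nodes) == 3

    def test_no_shared_mirna_gives_empty_network(self):
        net = assemble_cerna(
            pairs_frame([("L1", "G1")]),
            interactions([("L1", "m1")], "lncRNA", "miRNA"),
            interactions([("m2", "G1")], "miRNA", "mRNA"))
        assert net.triples == frozenset()

    def test_empty_pairs_warn_not_raise(self):
        net = assemble_cerna(pairs_frame([]),
                             interactions([], "lncRNA", "miRNA"),
                             interactions([], "miRNA", "mRNA"))
        assert net.triples == frozenset()

    def test_order_independence(self, small_net):
        pairs = pairs_frame([("L2", "G2"), ("L1", "G2"), ("L1", "G1")])
        lnc_mir = interactions([("L2", "m3"), ("L1", "m2"), ("L1", "m1")],
                               "lncRNA", "miRNA")
        mir_mrna = interactions([("m3", "G2"), ("m2", "G2"), ("m2", "G1"),
                                 ("m1", "G1")], "miRNA", "mRNA")
        assert assemble_cerna(pairs, lnc_mir, mir_mrna).triples == small_net.triples

    def test_adding_rows_never_removes_triples(self, small_net):
        lnc_mir = interactions([("L1", "m1"), ("L1", "m2"), ("L2", "m3"),
                                ("L2", "m2")], "lncRNA", "miRNA")
        mir_mrna = interactions([("m1", "G1"), ("m2", "G1"), ("m2", "G2"),
                                 ("m3", "G2"), ("m1", "G2")], "miRNA", "mRNA")
        grown = assemble_cerna(
            pairs_frame([("L1", "G1"), ("L1", "G2"), ("L2", "G2")]),
            lnc_mir, mir_mrna)
        assert small_net.triples <= grown.triples

    def test_every_triple_edge_present(self, small_net):
        for l, m, g in small_net.triples:
            assert (l, m) in small_net.lnc_mir_edges
            assert (m, g) in small_net.mir_mrna_edges


class TestDegreesAndHubs:
    def test_single_triple_degrees(self):
        net = CeRNANetwork(frozenset({("L1", "m1", "G1")}))
        assert node_degrees(net) == {"L1": 1, "m1": 2, "G1": 1}

    def test_lncrna_degree_counts_distinct_mirnas(self):
        triples = frozenset({("L1", f"m{i}", "G1") for i in range(5)})
        assert node_degrees(CeRNANetwork(triples))["L1"] == 5

    def test_handshake_lemma(self, small_net):
        degrees = node_degrees(small_net)
        assert sum(degrees.values()) == 2 * small_net.n_edges

    def test_threshold_semantics_and_ordering(self):
        triples = set()
        for lnc, k in [("L1", 21), ("L2", 20), ("L3", 36)]:
            triples |= {(lnc, f"{lnc}m{i}", "G1") for i in range(k)}
        hubs = hub_lncrnas(CeRNANetwork(frozenset(triples)), 20, ">")
        assert hubs.ids == ["L3", "L1"]

    def test_planted_hub_ranks_first(self, default_dataset, default_de):
        from cernascope.coexpression import coexpression_pairs
        pairs = coexpression_pairs(default_de, default_dataset.matrix)
        net = assemble_cerna(pairs, default_dataset.lnc_mir,
                             default_dataset.mir_mrna)
        hubs = hub_lncrnas(net)
        assert hubs.ids[0] == default_dataset.truth.hub_lncrna


class TestSubnetwork:
    def test_identity_annihilator_and_recount(self, small_net):
        assert extract_subnetwork(
            small_net, small_net.lncrna_nodes).triples == small_net.triples
        assert extract_subnetwork(small_net, []).triples == frozenset()
        sub = extract_subnetwork(small_net, ["L1"])
        assert sub.triples == {t for t in small_net.triples if t[0] == "L1"}
        # direct recount of the restriction's edges
        assert sub.edges == {e for t in small_net.triples if t[0] == "L1"
                             for e in [(t[0], t[1]), (t[1], t[2])]}

    def test_unknown_id_rejected(self, small_net):
        with pytest.raises(ValueError, match="LX"):
            extract_subnetwork(small_net, ["LX"])


class TestCoreMrnas:
    def test_set_algebra(self):
        core, table = core_mrnas({"a": {"A", "B", "C"}, "b": {"B", "C", "D"},
                                  "c": {"C", "B"}})
        assert core == {"B", "C"}
        assert set(table.loc[table["in_all"], "gene_id"]) == {"B", "C"}
        assert set(table.columns) == {"gene_id", "a", "b", "c", "in_all"}

    def test_disjoint_sets(self):
        core, _ = core_mrnas({"a": {"A"}, "b": {"B"}})
        assert core == set()

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            core_mrnas({"only": {"A"}})


class TestRoundTrips:
    def test_triples_tsv_round_trip(self, tmp_path, small_net):
        path = write_triples(small_net, tmp_path / "t.tsv")
        assert read_triples(path).triples == small_net.triples

    def test_sif_preserves_edges(self, tmp_path, small_net):
        path = write_sif(small_net, tmp_path / "n.sif")
        edges = read_sif(path)
        assert {(a, c) for a, _, c in edges} == small_net.edges
        assert {rel for _, rel, _ in edges} <= {"lnc-mir", "mir-mrna"}

    def test_graphml_preserves_nodes_edges_and_attrs(self, tmp_path, small_net):
        import networkx as nx
        from cernascope.cerna import write_graphml
        path = write_graphml(small_net, tmp_path / "n.graphml")
        g = nx.read_graphml(path)
        assert set(g.nodes) == set(small_net.lncrna_nodes
                                   | small_net.mirna_nodes
                                   | small_net.mrna_nodes)
        assert {frozenset(e) for e in g.edges} == {frozenset(e)
                                                   for e in small_net.edges}
        assert g.nodes["L1"]["node_type"] == "lncRNA"
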