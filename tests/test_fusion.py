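import numpy as np
import pytest

import taxafuse as tf
from taxafuse.fusion import (
    EnrichmentTable,
    TaxonomyRecord,
    build_name_map,
    build_network,
    convert_name,
    export_graph,
    import_graph,
    infuse_clusters,
    node_scores,
    read_taxonomy,
)


def record(otu, genus="Blautia"):
    return TaxonomyRecord(
        otu_id=otu,
        lineage=[
            ("domain", "Bacteria", 100),
            ("phylum", "Proteobacteria", 100),
            ("class", "Gammaproteobacteria", 100),
            ("order", "Enterobacteriales", 100),
            ("family", "Enterobacteriaceae", 100),
            ("genus", genus, 100),
        ],
    )


class TestConvertName:
    @pytest.mark.parametrize(
        "feature, expected",
        [
            ("c__Gammaproteobacteria", "Gammaproteobacteria"),
            ("f__Myxococcales.0319.6G20", "Myxococcales"),
            ("s__Myxococcales.sp", "Myxococcales"),
            ("p__Lentisphaerae", "Lentisphaerae"),
            ("o__Victivallales", "Victivallales"),
        ],
    )
    def test_mixed_level_names(self, feature, expected):
        assert convert_name(feature) == expected

    def test_unclassified_genus_ascends_to_family(self):
        rec = record("Otu00002", genus="unclassified")
        assert convert_name("Otu00002", rec) == "Enterobacteriaceae"

    def test_classified_genus_used_directly(self):
        assert convert_name("Otu00001", record("Otu00001")) == "Blautia"

    def test_unresolvable_feature_named_in_error(self):
        with pytest.raises(ValueError, match="Otu99999"):
            convert_name("Otu99999")

    def test_synonym_override(self):
        syn = {"s__distasonis": "Parabacteroides distasonis"}
        assert convert_name("s__distasonis", synonyms=syn) == "Parabacteroides distasonis"


class TestNameMap:
    def test_myxococcales_features_share_one_microbe(self):
        nm = build_name_map(["f__Myxococcales.0319.6G20", "s__Myxococcales.sp"])
        assert nm.inverse == {
            "Myxococcales": ["f__Myxococcales.0319.6G20", "s__Myxococcales.sp"]
        }

    def test_disjoint_names_stay_singletons(self):
        nm = build_name_map(["g__Rothia", "p__Lentisphaerae"])
        assert all(len(v) == 1 for v in nm.inverse.values())

    def test_inverse_partitions_features(self):
        feats = ["f__Myxococcales.0319.6G20", "s__Myxococcales.sp", "g__Rothia"]
        nm = build_name_map(feats)
        flat = [f for group in nm.inverse.values() for f in group]
        assert sorted(flat) == sorted(feats)


def two_study_table():
    return EnrichmentTable(
        records=[
            ("A", "colorectal cancer", frozenset({"m1", "m2"})),
            ("B", "colorectal cancer", frozenset({"m1"})),
        ]
    )


class TestBuildNetwork:
    def test_sizes_and_cooccurrence(self):
        net = build_network(two_study_table())
        assert net.node_size("m1") == 2 and net.node_size("m2") == 1
        assert net.edge_weight("m1", "m2") == 1

    def test_adjacency_symmetric_and_bounded(self):
        rng_names = [f"m{i}" for i in range(6)]
        table, _, _ = tf.make_enrichment(rng_names, n_studies=15, seed=2)
        net = build_network(table)
        net.validate()  # symmetry + weight <= min(node sizes)

    def test_edge_weights_order_cooccurrence(self):
        table = EnrichmentTable(
            records=[
                ("A", "crc", frozenset({"n1", "n2", "n3"})),
                ("B", "crc", frozenset({"n1", "n2"})),
                ("C", "crc", frozenset({"n1", "n3"})),
                ("D", "crc", frozenset({"n1", "n2"})),
            ]
        )
        net = build_network(table)
        # n1 co-occurs with n2 more often than with n3; edge weights agree
        assert net.edge_weight("n1", "n2") > net.edge_weight("n1", "n3")

    def test_disease_filter_substring_case_insensitive(self):
        table = EnrichmentTable(
            records=[
                ("A", "Colorectal Cancer", frozenset({"m1"})),
                ("B", "ulcerative colitis", frozenset({"m2"})),
            ]
        )
        net = build_network(table, disease="colorectal")
        assert "m1" in net.graph and "m2" not in net.graph

    def test_empty_filter_named(self):
        with pytest.raises(ValueError, match="parkinson"):
            build_network(two_study_table(), disease="parkinson")

    def test_invariant_to_record_order(self):
        recs = [
            ("A", "crc", frozenset({"m1", "m2"})),
            ("B", "crc", frozenset({"m2", "m3"})),
            ("C", "crc", frozenset({"m1"})),
        ]
        a = build_network(EnrichmentTable(records=recs)).adjacency()
        b = build_network(EnrichmentTable(records=recs[::-1])).adjacency()
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]


class TestInfuseClusters:
    def lentisphaeria_setup(self):
        table = EnrichmentTable(
            records=[("A", "crc", frozenset({"Lentisphaeria", "Blautia"}))]
        )
        net = build_network(table)
        feats = ["c__Lentisphaeria", "p__Lentisphaerae", "o__Victivallales"]
        nm = build_name_map(feats + ["g__Rothia", "s__mucilaginosa",
                                     "f__Myxococcales.0319.6G20", "s__Myxococcales.sp"])
        return net, nm

    def test_valid_cluster_infused_with_size_one_nodes(self):
        net, nm = self.lentisphaeria_setup()
        clusters = {"cluster_1": ["c__Lentisphaeria", "p__Lentisphaerae", "o__Victivallales"]}
        infuse_clusters(net, clusters, nm)
        for new in ("Lentisphaerae", "Victivallales"):
            assert net.node_size(new) == 1
            assert net.graph.nodes[new]["origin"] == "infused"
        cluster_edges = [
            (u, v) for u, v, d in net.graph.edges(data=True) if d.get("cluster")
        ]
        assert len(cluster_edges) == 3

    def test_invalid_cluster_leaves_network_unchanged(self):
        net, nm = self.lentisphaeria_setup()
        before = (set(net.graph.nodes), set(net.graph.edges))
        infuse_clusters(net, {"cluster_1": ["g__Rothia", "s__mucilaginosa"]}, nm)
        assert (set(net.graph.nodes), set(net.graph.edges)) == before

    def test_single_node_cluster_adds_nothing(self):
        table = EnrichmentTable(records=[("A", "crc", frozenset({"Myxococcales"}))])
        net = build_network(table)
        nm = build_name_map(["f__Myxococcales.0319.6G20", "s__Myxococcales.sp"])
        before = (set(net.graph.nodes), set(net.graph.edges))
        infuse_clusters(
            net, {"cluster_1": ["f__Myxococcales.0319.6G20", "s__Myxococcales.sp"]}, nm
        )
        assert (set(net.graph.nodes), set(net.graph.edges)) == before

    def test_idempotent(self):
        net, nm = self.lentisphaeria_setup()
        clusters = {"cluster_1": ["c__Lentisphaeria", "p__Lentisphaerae", "o__Victivallales"]}
        infuse_clusters(net, clusters, nm)
        snap = (
            dict(net.graph.nodes(data=True)),
            {(u, v): dict(d) for u, v, d in net.graph.edges(data=True)},
        )
        infuse_clusters(net, clusters, nm)
        snap2 = (
            dict(net.graph.nodes(data=True)),
            {(u, v): dict(d) for u, v, d in net.graph.edges(data=True)},
        )
        assert snap == snap2

    def test_existing_enrichment_edge_keeps_weight(self):
        table = EnrichmentTable(
            records=[
                ("A", "crc", frozenset({"Lentisphaeria", "Victivallales"})),
                ("B", "crc", frozenset({"Lentisphaeria", "Victivallales"})),
            ]
        )
        net = build_network(table)
        nm = build_name_map(["c__Lentisphaeria", "o__Victivallales"])
        infuse_clusters(net, {"c1": ["c__Lentisphaeria", "o__Victivallales"]}, nm)
        assert net.edge_weight("Lentisphaeria", "Victivallales") == 2
        assert net.graph.edges["Lentisphaeria", "Victivallales"]["cluster"] is True


class TestNodeScores:
    def test_mean_of_member_scores(self):
        net = build_network(
            EnrichmentTable(records=[("A", "crc", frozenset({"Myxococcales"}))])
        )
        nm = build_name_map(["f__Myxococcales.0319.6G20", "s__Myxococcales.sp"])
        node_scores(net, {"f__Myxococcales.0319.6G20": 5.0, "s__Myxococcales.sp": -2.0}, nm)
        assert net.graph.nodes["Myxococcales"]["score"] == pytest.approx(1.5)
        assert net.graph.nodes["Myxococcales"]["n_features"] == 2

    def test_singleton_node_score(self):
        net = build_network(EnrichmentTable(records=[("A", "crc", frozenset({"Rothia"}))]))
        nm = build_name_map(["g__Rothia"])
        node_scores(net, {"g__Rothia": -0.7}, nm)
        assert net.graph.nodes["Rothia"]["score"] == pytest.approx(-0.7)

    def test_invariant_to_member_order(self):
        net1 = build_network(EnrichmentTable(records=[("A", "crc", frozenset({"Myxococcales"}))]))
        net2 = build_network(EnrichmentTable(records=[("A", "crc", frozenset({"Myxococcales"}))]))
        feats = ["f__Myxococcales.0319.6G20", "s__Myxococcales.sp"]
        scores = {feats[0]: 3.0, feats[1]: 1.0}
        node_scores(net1, scores, build_name_map(feats))
        node_scores(net2, scores, build_name_map(feats[::-1]))
        assert (
            net1.graph.nodes["Myxococcales"]["score"]
            == net2.graph.nodes["Myxococcales"]["score"]
        )

    def test_unmapped_node_flagged_unscored(self):
        net = build_network(EnrichmentTable(records=[("A", "crc", frozenset({"Ghost"}))]))
        node_scores(net, {}, build_name_map([]))
        assert net.graph.nodes["Ghost"].get("unscored") is True
        assert "score" not in net.graph.nodes["Ghost"]


class TestExportImport:
    def _fused(self):
        net, nm = TestInfuseClusters().lentisphaeria_setup()
        infuse_clusters(
            net, {"cluster_1": ["c__Lentisphaeria", "p__Lentisphaerae", "o__Victivallales"]}, nm
        )
        node_scores(net, {"c__Lentisphaeria": 2.0}, nm)
        return net

    def test_graphml_round_trip(self, tmp_path):
        net = self._fused()
        path = export_graph(net, tmp_path / "net.graphml")
        back = import_graph(path)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert set(map(frozenset, back.graph.edges)) == set(map(frozenset, net.graph.edges))
        for n in net.graph.nodes:
            assert back.node_size(n) == net.node_size(n)
            if "score" in net.graph.nodes[n]:
                assert back.graph.nodes[n]["score"] == pytest.approx(
                    net.graph.nodes[n]["score"]
                )
            else:
                assert "score" not in back.graph.nodes[n]

    def test_cluster_edges_carry_origin(self, tmp_path):
        net = self._fused()
        back = import_graph(export_graph(net, tmp_path / "net.graphml"))
        origins = {d["origin"] for _, _, d in back.graph.edges(data=True)}
        assert "cluster" in origins

    def test_unscored_nodes_serialize_without_score(self, tmp_path):
        net = self._fused()
        back = import_graph(export_graph(net, tmp_path / "net.graphml"))
        assert "score" not in back.graph.nodes["Victivallales"]


class TestTaxonomyReader:
    def test_round_trip_with_generator(self, tmp_path):
        feats = [f"Otu{i:05d}" for i in range(1, 6)]
        records = tf.make_taxonomy(feats, unclassified_fraction=0.4, seed=1)
        path = tmp_path / "cons.taxonomy"
        from taxafuse.simulate import write_taxonomy

        write_taxonomy(records, path)
        back = read_taxonomy(path)
        assert set(back) == set(feats)
        for f in feats:
            assert back[f].deepest_classified() == records[f].deepest_classified()

    def test_mothur_example_lineage(self, tmp_path):
        p = tmp_path / "t.taxonomy"
        p.write_text(
            "OTU\tSize\tTaxonomy\n"
            "Otu000001\t100\tBacteria(100);Firmicutes(100);Clostridia(100);"
            "Clostridiales(100);Lachnospiraceae(100);Blautia(100);\n"
        )
        rec = read_taxonomy(p)["Otu000001"]
        assert rec.lineage[0] == ("domain", "Bacteria", 100)
        assert rec.deepest_classified() == "Blautia"
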