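"""Fuse data-driven clusters with a literature co-occurrence network.

Feature names are converted to plain microbe names (rank prefixes stripped,
unclassified OTUs ascend to their nearest classified ancestor); an enrichment
table yields nodes sized by study occurrence and edges weighted by
co-occurrence; valid clusters are infused as size-1 nodes and 'cluster'
edges; node scores are the mean member feature scores.
"""

import taxafuse as tf
from taxafuse.fusion import EnrichmentTable

features = [
    "c__Lentisphaeria", "p__Lentisphaerae", "o__Victivallales",
    "f__Myxococcales.0319.6G20", "s__Myxococcales.sp",
    "g__Rothia", "s__mucilaginosa",
]
name_map = tf.build_name_map(features)
print("name conversions:", name_map.forward)

table = EnrichmentTable(records=[
    ("study_1", "colorectal cancer", frozenset({"Lentisphaeria", "Myxococcales"})),
    ("study_2", "colorectal cancer", frozenset({"Myxococcales", "Blautia"})),
    ("study_3", "colorectal cancer", frozenset({"Lentisphaeria", "Myxococcales", "Blautia"})),
])
net = tf.build_network(table, disease="colorectal")
print(f"literature network: {net.graph.number_of_nodes()} nodes, "
      f"{net.graph.number_of_edges()} edges; "
      f"size(Myxococcales) = {net.node_size('Myxococcales')}")

clusters = {
    "cluster_1": ["c__Lentisphaeria", "p__Lentisphaerae", "o__Victivallales"],
    "cluster_2": ["g__Rothia", "s__mucilaginosa"],              # invalid: no anchor
    "cluster_3": ["f__Myxococcales.0319.6G20", "s__Myxococcales.sp"],  # one node already
}
tf.infuse_clusters(net, clusters, name_map)
infused = [n for n, d in net.graph.nodes(data=True) if d.get("origin") == "infused"]
print(f"infused nodes (size 1): {sorted(infused)}")

feature_scores = {"f__Myxococcales.0319.6G20": 5.0, "s__Myxococcales.sp": -2.0,
                  "c__Lentisphaeria": 1.0}
tf.node_scores(net, feature_scores, name_map)
print(f"node score Myxococcales = mean(5, -2) = "
      f"{net.graph.nodes['Myxococcales']['score']}")
# node size says how often the literature mentions a microbe; node score says
# how strongly its features track the outcome — the two prioritisation axes
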