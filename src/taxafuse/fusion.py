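"""Fusion of data-driven feature clusters with a literature co-occurrence
network of microbes.

Feature names — either mixed-level taxon strings such as ``c__Gammaproteobacteria``
or OTU ids with a mothur-style taxonomy — are converted to the plain microbe
names used by taxon-set enrichment results. An enrichment table (study id,
disease annotation, member microbes) yields an occurrence/co-occurrence
network: node size = number of studies mentioning the microbe, edge weight =
number of studies mentioning both endpoints. Feature clusters from the
density-clustering stage are then infused: a cluster is valid when at least
one member maps to an existing node; missing member names are added as new
nodes of size 1 and the cluster relation is recorded as ``origin="cluster"``
edges (the figures' red edges). Finally each node receives a score — the mean
of its member features' outcome-association scores.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TaxonomyRecord",
    "MicrobeNameMap",
    "EnrichmentTable",
    "FusedNetwork",
    "read_taxonomy",
    "read_enrichment",
    "convert_name",
    "build_name_map",
    "build_network",
    "infuse_clusters",
    "node_scores",
    "export_graph",
    "import_graph",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_MIXED_LEVEL = re.compile(r"^([a-zA-Z])__(.+)$")
_LINEAGE_SEG = re.compile(r"^(.*?)(?:\((\d+)\))?;?$")


@dataclass
class TaxonomyRecord:
    """One OTU's lineage, domain → genus, with per-rank support counts."""

    otu_id: str
    lineage: list[tuple[str, str, int]]   # (rank, name, support)

    def deepest_classified(self) -> str:
        """Name of the deepest rank not flagged 'unclassified'; ascends to the
        nearest classified ancestor otherwise."""
        for rank, name, _ in reversed(self.lineage):
            if name.lower() != "unclassified" and not name.lower().startswith("unclassified_"):
                return name
        raise ValueError(f"{self.otu_id}: no classified rank in lineage")


@dataclass
class MicrobeNameMap:
    forward: dict[str, str]               # feature → microbe name
    inverse: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.inverse:
            for feat, name in self.forward.items():
                self.inverse.setdefault(name, []).append(feat)


@dataclass
class EnrichmentTable:
    """Flat table of enrichment results: one record per study."""

    records: list[tuple[str, str, frozenset[str]]]   # (study id, disease, members)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("study ids must be unique")
        for sid, _, members in self.records:
            if not members:
                raise ValueError(f"study {sid!r} has an empty member set")


class FusedNetwork:
    """Wrapper around an undirected :class:`networkx.Graph` carrying node size
    (study occurrence count), node score (outcome association) and edge/node
    origin attributes."""

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()

    # -- views -------------------------------------------------------------
    def node_size(self, name: str) -> int:
        return int(self.graph.nodes[name]["size"])

    def edge_weight(self, u: str, v: str) -> int:
        return int(self.graph.edges[u, v]["weight"])

    def adjacency(self) -> tuple[np.ndarray, list[str]]:
        """Symmetric integer matrix: co-occurrence counts off the diagonal,
        occurrence counts on it."""
        nodes = sorted(self.graph.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)), dtype=int)
        for n in nodes:
            A[idx[n], idx[n]] = self.graph.nodes[n]["size"]
        for u, v, d in self.graph.edges(data=True):
            A[idx[u], idx[v]] = A[idx[v], idx[u]] = d["weight"]
        return A, nodes

    def validate(self) -> None:
        A, nodes = self.adjacency()
        if not np.array_equal(A, A.T):
            raise AssertionError("adjacency not symmetric")
        for u, v, d in self.graph.edges(data=True):
            if d.get("origin") == "enrichment":
                cap = min(self.node_size(u), self.node_size(v))
                if d["weight"] > cap:
                    raise AssertionError(f"edge ({u},{v}) weight exceeds node sizes")


def convert_name(
    feature: str,
    taxonomy: TaxonomyRecord | None = None,
    synonyms: dict[str, str] | None = None,
) -> str:
    """Convert a feature name to the plain microbe name used by enrichment
    databases.

    Mixed-level names (``x__Name``) drop the rank prefix and any trailing
    qualifier after the base clade token (strain suffixes, ``.sp`` endings):
    ``f__Myxococcales.0319.6G20`` and ``s__Myxococcales.sp`` both map to
    ``Myxococcales``. OTU ids resolve to the deepest classified rank of their
    taxonomy record, ascending past 'unclassified' levels. ``synonyms`` lets
    callers override individual conversions (e.g. species epithets that need
    their genus restored).
    """
    if synonyms and feature in synonyms:
        return synonyms[feature]
    m = _MIXED_LEVEL.match(feature)
    if m:
        base = m.group(2).split(".")[0].strip()
        if not base:
            raise ValueError(f"cannot extract a clade name from {feature!r}")
        if synonyms and base in synonyms:
            return synonyms[base]
        return base
    if taxonomy is not None:
        name = taxonomy.deepest_classified()
        if synonyms and name in synonyms:
            return synonyms[name]
        return name
    raise ValueError(
        f"feature {feature!r} is neither an 'x__Name' pattern nor an OTU with a taxonomy record"
    )


def build_name_map(
    features: list[str],
    taxonomy: dict[str, TaxonomyRecord] | None = None,
    synonyms: dict[str, str] | None = None,
) -> MicrobeNameMap:
    """Total feature → microbe-name map; the inverse groups features sharing a
    converted name (e.g. the two Myxococcales features become one microbe)."""
    taxonomy = taxonomy or {}
    forward = {
        feat: convert_name(feat, taxonomy.get(feat), synonyms) for feat in features
    }
    return MicrobeNameMap(forward=forward)


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyRecord]:
    """Parse a mothur-style constaxonomy file (columns OTU, Size, Taxonomy;
    lineage as ``Name(confidence);`` segments, domain → genus)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "otu" not in cols or "taxonomy" not in cols:
        raise ValueError(f"{path}: expected OTU and Taxonomy columns, got {list(df.columns)}")
    records: dict[str, TaxonomyRecord] = {}
    for _, row in df.iterrows():
        otu = str(row[cols["otu"]])
        segments = [s for s in str(row[cols["taxonomy"]]).split(";") if s.strip()]
        lineage: list[tuple[str, str, int]] = []
        for rank, seg in zip(RANKS, segments):
            m = _LINEAGE_SEG.match(seg.strip())
            name = m.group(1).strip()
            support = int(m.group(2)) if m.group(2) else 0
            if support < 0:
                raise ValueError(f"{otu}: negative support in {seg!r}")
            lineage.append((rank, name, support))
        records[otu] = TaxonomyRecord(otu_id=otu, lineage=lineage)
    return records


def read_enrichment(path: str | Path) -> EnrichmentTable:
    """Read an enrichment-results CSV: columns study, disease, members
    (semicolon-joined microbe names)."""
    records: list[tuple[str, str, frozenset[str]]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        lower = {c.lower(): c for c in reader.fieldnames or []}
        for key in ("study", "disease", "members"):
            if key not in lower:
                raise ValueError(f"{path}: missing column {key!r}")
        for row in reader:
            members = frozenset(
                m.strip() for m in row[lower["members"]].split(";") if m.strip()
            )
            records.append((row[lower["study"]].strip(), row[lower["disease"]].strip(), members))
    return EnrichmentTable(records=records)


def build_network(table: EnrichmentTable, disease: str | None = None) -> FusedNetwork:
    """Occurrence/co-occurrence network from enrichment records.

    ``disease`` filters studies by case-insensitive substring match. Node size
    = number of retained studies containing the microbe; edge weight = number
    containing both endpoints; zero-weight pairs are omitted.
    """
    records = table.records
    if disease is not None:
        needle = disease.lower()
        records = [r for r in records if needle in r[1].lower()]
        if not records:
            raise ValueError(f"no studies match disease filter {disease!r}")
    g = nx.Graph()
    member_sets = [members for _, _, members in records]
    for members in member_sets:
        for m in members:
            if m in g:
                g.nodes[m]["size"] += 1
            else:
                g.add_node(m, size=1, origin="enrichment")
    for members in member_sets:
        ordered = sorted(members)
        for i, u in enumerate(ordered):
            for v in ordered[i + 1 :]:
                if g.has_edge(u, v):
                    g.edges[u, v]["weight"] += 1
                else:
                    g.add_edge(u, v, weight=1, origin="enrichment")
    return FusedNetwork(g)


def infuse_clusters(
    net: FusedNetwork,
    clusters: dict[str, list[str]],
    name_map: MicrobeNameMap,
) -> FusedNetwork:
    """Add valid data-driven clusters to the network (idempotent).

    A cluster is valid iff at least one member feature's converted name is an
    existing node. Valid clusters contribute their absent member names as new
    nodes (size 1, ``origin="infused"``) and ``origin="cluster"`` edges between
    every pair of the cluster's node names; an existing enrichment edge keeps
    its weight and gains a ``cluster=True`` marker. Clusters whose members all
    collapse to a single node name contribute nothing; clusters with more than
    one member column in ``clusters`` but only singleton provenance are skipped.
    """
    g = net.graph
    for _, members in sorted(clusters.items()):
        if len(members) < 2:
            continue  # singleton provenance: nothing to relate
        try:
            names = sorted({name_map.forward[f] for f in members})
        except KeyError as exc:
            raise KeyError(f"cluster member {exc} has no converted name") from exc
        if len(names) < 2:
            continue  # all members form one microbial node already
        if not any(name in g for name in names):
            continue  # invalid cluster: no anchor in the literature network
        for name in names:
            if name not in g:
                g.add_node(name, size=1, origin="infused")
        for i, u in enumerate(names):
            for v in names[i + 1 :]:
                if g.has_edge(u, v):
                    g.edges[u, v]["cluster"] = True
                else:
                    g.add_edge(u, v, weight=1, origin="cluster", cluster=True)
    return net


def node_scores(
    net: FusedNetwork,
    feature_scores: dict[str, float],
    name_map: MicrobeNameMap,
) -> FusedNetwork:
    """score(node) = mean of its member features' scores (n = member count);
    nodes with no scored member features are flagged unscored."""
    for node in net.graph.nodes:
        members = [f for f in name_map.inverse.get(node, []) if f in feature_scores]
        if members:
            net.graph.nodes[node]["score"] = float(
                np.mean([feature_scores[f] for f in members])
            )
            net.graph.nodes[node]["n_features"] = len(members)
        else:
            net.graph.nodes[node].pop("score", None)
            net.graph.nodes[node]["unscored"] = True
    return net


def export_graph(net: FusedNetwork, path: str | Path, fmt: str | None = None) -> Path:
    """Write the network as GraphML (or GML); attributes survive a round-trip
    through :func:`import_graph`. Nodes without a score serialize without a
    score attribute."""
    path = Path(path)
    if fmt is None:
        fmt = "gml" if path.suffix.lower() == ".gml" else "graphml"
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "gml":
        nx.write_gml(net.graph, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
    return path


def import_graph(path: str | Path) -> FusedNetwork:
    path = Path(path)
    if path.suffix.lower() == ".gml":
        g = nx.read_gml(path)
    else:
        g = nx.read_graphml(path)
    for _, d in g.nodes(data=True):
        d["size"] = int(d["size"])
    for _, _, d in g.edges(data=True):
        d["weight"] = int(d["weight"])
    return FusedNetwork(g)
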