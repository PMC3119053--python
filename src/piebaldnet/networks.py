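"""Regulatory (TFBS) and epistatic gene networks, hub reduction, intersection.

The regulatory network links a transcription factor to a candidate gene when
a high-confidence binding site (core and matrix similarity at or above the
confidence threshold, default 1.0) is recorded in the gene's promoter.  The
epistatic network links the nearest genes of the two SNPs in each significant
pair.  Hubs are genes participating in strictly more than ``hub_threshold``
significant pairs; the reduced network keeps only edges incident to a hub.
The intersecting landscape is the set of gene-typed nodes present in both
networks (TF nodes never count).

Networks are stored undirected in :class:`networkx.Graph` objects; the
TF-to-gene direction survives as an edge annotation for export.  Exports are
Cytoscape-compatible: SIF, GraphML, and a node-attribute TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .annotation import SnpGeneMapping

GENE = "gene"
TF = "tf"
EDGE_TFBS = "tfbs"
EDGE_EPISTASIS = "epistasis"
ABSENT = "absent"

DEFAULT_HUB_THRESHOLD = 20
DEFAULT_TFBS_CONFIDENCE = 1.0


@dataclass
class GeneNetwork:
    """Undirected typed network of genes (and TFs) with colour attributes."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_node(self, node_id: str, node_type: str, colour: str = ABSENT) -> None:
        self.graph.add_node(node_id, node_type=node_type, colour_category=colour)

    def add_edge(self, a: str, b: str, edge_type: str, **annotation) -> None:
        if a == b:
            raise ValueError(f"self-edge on node {a!r}")
        for n in (a, b):
            if n not in self.graph:
                raise ValueError(f"edge endpoint {n!r} is not a node")
        self.graph.add_edge(a, b, edge_type=edge_type, **annotation)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def gene_nodes(self) -> set:
        return {
            n for n, d in self.graph.nodes(data=True) if d.get("node_type") == GENE
        }

    def degree(self, node_id: str) -> int:
        return int(self.graph.degree[node_id])


@dataclass
class HubSet:
    """Genes participating in more than ``threshold`` significant pairs."""

    counts: dict
    threshold: int

    @property
    def hub_ids(self) -> set:
        return set(self.counts)


# ---------------------------------------------------------------------------
# Construction


def _colour_map(de_results) -> dict:
    return {r.gene_id: r.colour_category for r in de_results or ()}


def build_regulatory_network(
    tfbs: pd.DataFrame,
    candidate_genes,
    de_results=None,
    min_confidence: float = DEFAULT_TFBS_CONFIDENCE,
    min_targets: int = 1,
) -> GeneNetwork:
    """TF-to-gene network from high-confidence binding sites in candidate genes.

    Keeps TFBS records with core AND matrix similarity >= ``min_confidence``
    whose target gene is a candidate; a TF becomes a node when it links at
    least ``min_targets`` candidate genes.  Gene nodes (all candidates, even
    unconnected) are coloured from the DE results: over / under / unchanged,
    or absent for genes never measured on the array.
    """
    candidate_genes = list(candidate_genes)
    if not candidate_genes:
        raise ValueError("candidate gene set is empty")
    colours = _colour_map(de_results)
    net = GeneNetwork()
    for gene in candidate_genes:
        net.add_node(gene, GENE, colours.get(gene, ABSENT))

    if tfbs is None or tfbs.empty:
        return net
    keep = (
        (tfbs["core_similarity"] >= min_confidence)
        & (tfbs["matrix_similarity"] >= min_confidence)
        & tfbs["gene_id"].isin(set(candidate_genes))
    )
    kept = tfbs[keep]
    by_tf = kept.groupby("tf_name")["gene_id"].agg(lambda s: sorted(set(s)))
    for tf, targets in by_tf.items():
        if len(targets) < min_targets:
            continue
        net.add_node(tf, TF, colours.get(tf, ABSENT))
        for gene in targets:
            if tf == gene:
                continue
            net.add_edge(tf, gene, EDGE_TFBS, direction=f"{tf}->{gene}")
    return net


def build_epistatic_network(
    pairs,
    mappings: list[SnpGeneMapping],
    de_results=None,
    hub_threshold: int = DEFAULT_HUB_THRESHOLD,
    exclude_proximal: bool = False,
) -> tuple[GeneNetwork, HubSet]:
    """Gene network from significant SNP pairs via their nearest genes.

    Each significant pair becomes an edge between the nearest genes of its
    two SNPs; pairs collapsing onto one gene are dropped as self-edges, and
    pairs flagged as physically proximal (<100 kb) can be excluded.  Several
    pairs mapping to one gene pair collapse to a single edge annotated with
    the pair count.  A hub is a gene participating in strictly more than
    ``hub_threshold`` significant pairs (tallied per gene before edge
    collapsing).  Returns the full network and the hub set; see
    :func:`reduce_by_hubs` for the hub-reduced extraction.
    """
    nearest = {m.snp_id: m.nearest_gene_id for m in mappings}
    colours = _colour_map(de_results)

    pair_counts: dict[str, int] = {}
    edge_pairs: dict[tuple[str, str], list] = {}
    for rec in pairs:
        if not rec.significant:
            continue
        if exclude_proximal and rec.proximity_flag:
            continue
        genes = []
        for snp in (rec.snp_a, rec.snp_b):
            if snp not in nearest or nearest[snp] is None:
                raise ValueError(f"SNP {snp!r} in a significant pair has no gene mapping")
            genes.append(nearest[snp])
        ga, gb = sorted(genes)
        for g in {ga, gb}:
            pair_counts[g] = pair_counts.get(g, 0) + 1
        if ga == gb:
            continue  # both SNPs nearest to the same gene
        edge_pairs.setdefault((ga, gb), []).append((rec.snp_a, rec.snp_b))

    net = GeneNetwork()
    for (ga, gb), snp_pairs in edge_pairs.items():
        for g in (ga, gb):
            if g not in net.graph:
                net.add_node(g, GENE, colours.get(g, ABSENT))
        net.add_edge(
            ga,
            gb,
            EDGE_EPISTASIS,
            pair_count=len(snp_pairs),
            snp_pairs=";".join(f"{a}|{b}" for a, b in snp_pairs),
        )
    hubs = HubSet(
        counts={g: c for g, c in sorted(pair_counts.items()) if c > hub_threshold},
        threshold=hub_threshold,
    )
    return net, hubs


def reduce_by_hubs(network: GeneNetwork, hubs: HubSet) -> GeneNetwork:
    """Extract the sub-network of edges incident to at least one hub."""
    reduced = GeneNetwork()
    hub_ids = hubs.hub_ids
    for a, b, data in network.graph.edges(data=True):
        if a in hub_ids or b in hub_ids:
            for n in (a, b):
                if n not in reduced.graph:
                    attrs = network.graph.nodes[n]
                    reduced.add_node(
                        n, attrs.get("node_type", GENE), attrs.get("colour_category", ABSENT)
                    )
            reduced.graph.add_edge(a, b, **data)
    return reduced


def intersect_networks(
    regulatory: GeneNetwork, epistatic: GeneNetwork
) -> tuple[set, GeneNetwork]:
    """Gene-typed nodes common to both networks, and the merged landscape.

    TF nodes never count toward the intersection, and a gene is considered
    part of a network only when it is linked there (degree >= 1): candidate
    genes that no TF binds are carried in the regulatory network as isolated,
    coloured nodes for display, but belonging to the network in the
    intersection sense means being wired into it.  The merged network is the
    union of nodes and edges with intersection members tagged
    ``in_intersection``.
    """

    def linked_genes(net: GeneNetwork) -> set:
        return {n for n in net.gene_nodes() if net.graph.degree[n] > 0}

    common = linked_genes(regulatory) & linked_genes(epistatic)
    merged = GeneNetwork()
    for src in (regulatory, epistatic):
        for n, d in src.graph.nodes(data=True):
            if n not in merged.graph:
                merged.add_node(n, d.get("node_type", GENE), d.get("colour_category", ABSENT))
        for a, b, d in src.graph.edges(data=True):
            merged.graph.add_edge(a, b, **d)
    for n in merged.graph.nodes:
        merged.graph.nodes[n]["in_intersection"] = n in common
    return common, merged


# ---------------------------------------------------------------------------
# Export / import


def node_attribute_frame(network: GeneNetwork) -> pd.DataFrame:
    rows = [
        {
            "node_id": n,
            "node_type": d.get("node_type", GENE),
            "colour_category": d.get("colour_category", ABSENT),
            "degree": network.degree(n),
            "in_intersection": bool(d.get("in_intersection", False)),
        }
        for n, d in sorted(network.graph.nodes(data=True))
    ]
    return pd.DataFrame(
        rows, columns=["node_id", "node_type", "colour_category", "degree", "in_intersection"]
    )


def export_network(network: GeneNetwork, path, format: str = "sif") -> Path:
    """Write the network as SIF, GraphML, or a node-attribute TSV."""
    path = Path(path)
    if format == "sif":
        lines = [
            f"{a}\t{d.get('edge_type', 'link')}\t{b}"
            for a, b, d in sorted(network.graph.edges(data=True))
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "graphml":
        g = network.graph.copy()
        for n in g.nodes:
            g.nodes[n].setdefault("degree", network.degree(n))
            g.nodes[n]["in_intersection"] = bool(g.nodes[n].get("in_intersection", False))
        nx.write_graphml(g, path)
    elif format == "tsv":
        node_attribute_frame(network).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network export format {format!r}")
    return path


def read_network(path, format: str = "graphml", node_attributes=None) -> GeneNetwork:
    """Round-trip reader for exported networks.

    For SIF input, node types and colours can be restored from a
    node-attribute TSV written by :func:`export_network`.
    """
    path = Path(path)
    net = GeneNetwork()
    if format == "graphml":
        g = nx.read_graphml(path)
        for n, d in g.nodes(data=True):
            net.add_node(str(n), d.get("node_type", GENE), d.get("colour_category", ABSENT))
            if "in_intersection" in d:
                net.graph.nodes[str(n)]["in_intersection"] = bool(d["in_intersection"])
        for a, b, d in g.edges(data=True):
            net.graph.add_edge(str(a), str(b), **d)
        return net
    if format == "sif":
        attrs = {}
        if node_attributes is not None:
            df = pd.read_csv(node_attributes, sep="\t")
            attrs = {
                str(r.node_id): (r.node_type, r.colour_category)
                for r in df.itertuples(index=False)
            }
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            a, edge_type, b = line.split("\t")
            for n in (a, b):
                if n not in net.graph:
                    t, c = attrs.get(n, (GENE, ABSENT))
                    net.add_node(n, t, c)
            net.graph.add_edge(a, b, edge_type=edge_type)
        return net
    raise ValueError(f"unknown network import format {format!r}")
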