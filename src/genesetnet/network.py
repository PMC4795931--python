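"""Composite typed molecular interaction networks around a query gene list.

Four edge families are merged into one graph: protein–protein interactions
(only the high-confidence direct-physical class), miRNA→target interactions,
protein–compound interactions (compound groups keyed by InChIKey skeleton)
and TF→target regulatory edges.  The network is one-hop: nodes are the query
genes plus their direct partners of each type.  PPI and PCI edges are
undirected; MTI (miRNA→gene) and TF→target edges are directed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import networkx as nx

from .compounds import PCIEdge
from .ppi import PPIClassified, canonical_pair
from .types import GeneList, GenesetnetError, MTIRecord, TFTargetRecord

NodeKind = Literal["gene", "mirna", "compound_group"]
EdgeType = Literal["ppi", "mti", "pci", "tf_target"]

DIRECTED_TYPES = frozenset({"mti", "tf_target"})


@dataclass
class TypedNetwork:
    """Heterogeneous graph with typed nodes and (pair, type)-unique edges.

    Edge keys are (a, b, edge_type); undirected pairs are stored in
    canonical (lexicographic) order, directed ones as (source, target).
    """

    nodes: dict[str, str] = field(default_factory=dict)  # id -> kind
    edges: dict[tuple[str, str, str], dict] = field(default_factory=dict)
    query: set[str] = field(default_factory=set)

    def add_node(self, node_id: str, kind: str) -> None:
        prev = self.nodes.get(node_id)
        if prev is not None and prev != kind:
            raise GenesetnetError(f"node {node_id!r} declared both {prev} and {kind}")
        self.nodes[node_id] = kind

    def add_edge(self, a: str, b: str, edge_type: str, **attrs) -> None:
        if edge_type not in ("ppi", "mti", "pci", "tf_target"):
            raise GenesetnetError(f"unknown edge type {edge_type!r}")
        if edge_type not in DIRECTED_TYPES:
            a, b = canonical_pair(a, b)
        key = (a, b, edge_type)
        if a not in self.nodes or b not in self.nodes:
            raise GenesetnetError(f"edge {key} references an unknown node")
        self.edges.setdefault(key, {}).update(attrs)

    def degree_of(self, node_id: str) -> int:
        return sum(1 for a, b, _ in self.edges if node_id in (a, b))

    def edge_count_by_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, _, t in self.edges:
            out[t] = out.get(t, 0) + 1
        return out


def build_network(
    genes: GeneList,
    ppi: Iterable[PPIClassified] = (),
    mti: Iterable[MTIRecord] = (),
    pci: Iterable[PCIEdge] = (),
    tf: Iterable[TFTargetRecord] = (),
) -> TypedNetwork:
    """Assemble the one-hop composite network around the query genes.

    PPI edges are restricted to the high-confidence direct-physical class;
    an edge of any type is included iff at least one endpoint is a query
    gene.  Query genes are always present as nodes, even when isolated.
    """
    if len(genes) == 0:
        raise GenesetnetError("empty query gene list")
    net = TypedNetwork(query=set(genes))
    for g in genes:
        net.add_node(g, "gene")

    for c in ppi:
        if not c.direct_physical:
            continue
        a, b = c.pair
        if a in net.query or b in net.query:
            net.add_node(a, "gene")
            net.add_node(b, "gene")
            net.add_edge(a, b, "ppi", confidence="high_confidence_direct_physical")
    for m in mti:
        if m.gene_id in net.query or m.mirna_id in net.query:
            net.add_node(m.mirna_id, "mirna")
            net.add_node(m.gene_id, "gene")
            net.add_edge(m.mirna_id, m.gene_id, "mti", evidence_class=m.evidence_class)
    for e in pci:
        if e.protein_id in net.query:
            net.add_node(e.skeleton, "compound_group")
            net.add_node(e.protein_id, "gene")
            net.add_edge(
                e.skeleton,
                e.protein_id,
                "pci",
                best_activity_nM=e.best_activity_nM,
                drug_annotation=e.drug_annotation,
                source_dbs=";".join(sorted(e.source_dbs)),
            )
    for t in tf:
        if t.tf_gene_id in net.query or t.target_gene_id in net.query:
            net.add_node(t.tf_gene_id, "gene")
            net.add_node(t.target_gene_id, "gene")
            net.add_edge(t.tf_gene_id, t.target_gene_id, "tf_target", source_db=t.source_db)
    return net


def filter_activity(net: TypedNetwork, max_nM: float) -> TypedNetwork:
    """Drop assay-backed PCI edges weaker than the activity threshold.

    A PCI edge is removed iff it is not a drug-annotation edge and its best
    activity is absent or exceeds ``max_nM``.  Other edge types are never
    touched.  Nodes orphaned by the removal are pruned unless they are query
    genes, which anchor the display and are always retained.
    """
    if max_nM <= 0:
        raise GenesetnetError("max_nM must be positive")
    out = TypedNetwork(nodes=dict(net.nodes), query=set(net.query))
    for (a, b, t), attrs in net.edges.items():
        if t == "pci" and not attrs.get("drug_annotation", False):
            act = attrs.get("best_activity_nM")
            if act is None or act > max_nM:
                continue
        out.edges[(a, b, t)] = dict(attrs)
    connected = {x for a, b, _ in out.edges for x in (a, b)}
    out.nodes = {
        n: k for n, k in out.nodes.items() if n in connected or n in out.query
    }
    return out


def to_networkx(net: TypedNetwork) -> nx.MultiDiGraph:
    """Lossless conversion; undirected edges carry directed='false'."""
    g = nx.MultiDiGraph()
    for n, kind in net.nodes.items():
        g.add_node(n, node_kind=kind, is_query=n in net.query)
    for (a, b, t), attrs in net.edges.items():
        clean = {k: v for k, v in attrs.items() if v is not None}
        g.add_edge(a, b, key=t, edge_type=t,
                   directed=t in DIRECTED_TYPES, **clean)
    return g


def export_network(
    net: TypedNetwork,
    path: Union[str, Path],
    fmt: Literal["graphml", "sif", "json"] = "graphml",
) -> None:
    """Write the network as GraphML, SIF or Cytoscape-style JSON."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(to_networkx(net), path)
    elif fmt == "sif":
        lines = [f"{a}\t{t}\t{b}" for (a, b, t) in sorted(net.edges)]
        isolated = sorted(set(net.nodes) - {x for a, b, _ in net.edges for x in (a, b)})
        lines += isolated
        path.write_text("".join(l + "\n" for l in lines))
    elif fmt == "json":
        elements = {
            "nodes": [
                {"data": {"id": n, "node_kind": k, "is_query": n in net.query}}
                for n, k in sorted(net.nodes.items())
            ],
            "edges": [
                {
                    "data": {
                        "source": a,
                        "target": b,
                        "edge_type": t,
                        "directed": t in DIRECTED_TYPES,
                        **{k: v for k, v in attrs.items() if v is not None},
                    }
                }
                for (a, b, t), attrs in sorted(net.edges.items())
            ],
        }
        path.write_text(json.dumps({"elements": elements}, indent=1) + "\n")
    else:
        raise GenesetnetError(f"unknown export format {fmt!r}")


def read_network_graphml(path: Union[str, Path]) -> TypedNetwork:
    """Read back a GraphML file written by :func:`export_network`."""
    g = nx.read_graphml(path, force_multigraph=True)
    net = TypedNetwork()
    for n, d in g.nodes(data=True):
        net.nodes[n] = d.get("node_kind", "gene")
        if d.get("is_query"):
            net.query.add(n)
    for a, b, key, d in g.edges(keys=True, data=True):
        t = d.get("edge_type", key)
        attrs = {k: v for k, v in d.items() if k not in ("edge_type", "directed")}
        if t not in DIRECTED_TYPES:
            a, b = canonical_pair(a, b)
        net.edges[(a, b, t)] = attrs
    return net
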