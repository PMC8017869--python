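"""Knowledge graph of candidate feature encodings.

Nodes represent encodings of variant data at increasing levels of
abstraction — a single SNP locus, the exon/UTR/transcript/gene that
contains it, catch-all annotated regions and peptides, and Gene Ontology
terms grafted on top of genes.  Every edge points child -> parent, where
the parent is the higher (more abstract) representation.  The graph is a
DAG and may be disconnected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
from intervaltree import IntervalTree

NODE_KINDS = ("snp", "exon", "transcript", "gene", "utr", "peptide", "bio_region", "go_term")
COMBINE_RULES = ("leaf", "or", "threshold")

#: structural kinds a SNP may attach to before falling back to the gene
SUBGENE_KINDS = ("exon", "utr", "bio_region", "peptide")


@dataclass
class FeatureNode:
    """One candidate feature encoding with its per-sample binary vector."""

    node_id: str
    kind: str
    label: str = ""
    #: (chrom, start, end), 0-based half-open; None for GO terms
    interval: Optional[tuple] = None
    #: n-sample boolean vector B_i, assigned by the encoding stage
    vector: Optional[np.ndarray] = None
    combine_rule: str = "or"
    #: gene ids feeding a threshold (GO leaf) node
    genes: tuple = ()

    def __post_init__(self):
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.combine_rule not in COMBINE_RULES:
            raise ValueError(f"unknown combine rule {self.combine_rule!r}")


class KnowledgeGraph:
    """Directed acyclic graph over :class:`FeatureNode` objects.

    Edges are stored child -> parent.  ``alias`` maps node ids merged
    during redundancy collapsing to their surviving node id.
    """

    def __init__(self):
        self._g = nx.DiGraph()
        self.nodes: dict[str, FeatureNode] = {}
        self.alias: dict[str, str] = {}

    # -- construction -------------------------------------------------
    def add_node(self, node: FeatureNode) -> FeatureNode:
        if node.node_id in self.nodes:
            return self.nodes[node.node_id]
        self.nodes[node.node_id] = node
        self._g.add_node(node.node_id)
        return node

    def add_edge(self, child: str, parent: str) -> None:
        if child not in self.nodes or parent not in self.nodes:
            raise KeyError(f"edge ({child!r}, {parent!r}) references unknown node")
        if child == parent:
            raise ValueError(f"self-loop on {child!r}")
        self._g.add_edge(child, parent)

    def remove_node(self, node_id: str) -> None:
        self._g.remove_node(node_id)
        del self.nodes[node_id]

    # -- queries ------------------------------------------------------
    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._g.edges())

    def parents(self, node_id: str) -> list[str]:
        return sorted(self._g.successors(node_id))

    def children(self, node_id: str) -> list[str]:
        return sorted(self._g.predecessors(node_id))

    def ancestors(self, node_id: str) -> set[str]:
        """All higher abstractions reachable from ``node_id``."""
        return nx.descendants(self._g, node_id)

    def roots(self) -> list[str]:
        return sorted(n for n in self._g if self._g.out_degree(n) == 0)

    def leaves(self) -> list[str]:
        return sorted(n for n in self._g if self._g.in_degree(n) == 0)

    def topological_order(self) -> list[str]:
        """Children before parents (leaves first)."""
        try:
            return list(nx.lexicographical_topological_sort(self._g))
        except nx.NetworkXUnfeasible as exc:
            raise ValueError("knowledge graph contains a cycle") from exc

    def check_acyclic(self) -> None:
        if not nx.is_directed_acyclic_graph(self._g):
            raise ValueError("knowledge graph contains a cycle")

    def has_path(self, src: str, dst: str) -> bool:
        return nx.has_path(self._g, src, dst)

    def resolve(self, node_id: str) -> str:
        """Follow the alias map to the surviving node id."""
        seen = set()
        while node_id in self.alias:
            if node_id in seen:  # defensive; aliases are compressed on merge
                raise ValueError("alias cycle")
            seen.add(node_id)
            node_id = self.alias[node_id]
        return node_id

    def copy(self) -> "KnowledgeGraph":
        out = KnowledgeGraph()
        for nid, node in self.nodes.items():
            out.add_node(FeatureNode(
                node_id=node.node_id, kind=node.kind, label=node.label,
                interval=node.interval,
                vector=None if node.vector is None else node.vector.copy(),
                combine_rule=node.combine_rule, genes=node.genes,
            ))
        for u, v in self._g.edges():
            out.add_edge(u, v)
        out.alias = dict(self.alias)
        return out

    def equals(self, other: "KnowledgeGraph") -> bool:
        """Node-for-node, edge-for-edge, bit-for-bit equality."""
        if set(self.nodes) != set(other.nodes) or self.edges != other.edges:
            return False
        if self.alias != other.alias:
            return False
        for nid, a in self.nodes.items():
            b = other.nodes[nid]
            if (a.kind, a.label, a.interval, a.combine_rule) != (b.kind, b.label, b.interval, b.combine_rule):
                return False
            if (a.vector is None) != (b.vector is None):
                return False
            if a.vector is not None and not np.array_equal(a.vector, b.vector):
                return False
        return True


def _intervals_overlap(a: Optional[tuple], b: Optional[tuple]) -> bool:
    if a is None or b is None:
        return False
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def variant_node_id(chrom: str, pos0: int) -> str:
    """Node id of a variant locus; shown 1-based as in VCF."""
    return f"{chrom}:{pos0 + 1}"


def build_genomic_hierarchy(annotations, variants) -> KnowledgeGraph:
    """Build the annotation-derived hierarchy and attach variant loci.

    Edges follow containment/abstraction: exon -> transcript -> gene,
    UTR -> transcript (or gene when no transcript parent is known),
    peptide/bio_region -> every overlapping gene.  Each distinct variant
    locus becomes a SNP node with an edge to every *smallest* containing
    sub-gene element; a SNP inside a gene but outside all sub-gene
    elements links directly to the gene; a SNP overlapping nothing stays
    an isolated leaf.
    """
    annotations = list(annotations)
    variants = list(variants)
    kg = KnowledgeGraph()
    by_id: dict[str, object] = {}
    for rec in annotations:
        by_id[rec.id] = rec
        kg.add_node(FeatureNode(
            node_id=rec.id, kind=rec.feature_type, label=rec.id,
            interval=(rec.chrom, rec.start, rec.end),
        ))

    gene_recs = [r for r in annotations if r.feature_type == "gene"]

    for rec in annotations:
        if rec.feature_type in ("peptide", "bio_region"):
            hit = False
            for g in gene_recs:
                if _intervals_overlap((rec.chrom, rec.start, rec.end), (g.chrom, g.start, g.end)):
                    kg.add_edge(rec.id, g.id)
                    hit = True
            continue
        if rec.feature_type == "gene" or rec.parent_id is None:
            continue
        parent = by_id.get(rec.parent_id)
        if parent is None:
            warnings.warn(f"{rec.id}: parent {rec.parent_id!r} not found; kept as orphan root")
            continue
        if rec.feature_type == "utr" and parent.feature_type not in ("transcript", "gene"):
            warnings.warn(f"UTR {rec.id} parent {parent.id} has type {parent.feature_type}; kept as orphan")
            continue
        kg.add_edge(rec.id, parent.id)

    # interval index over sub-gene structural elements, per chromosome
    sub_trees: dict[str, IntervalTree] = {}
    gene_trees: dict[str, IntervalTree] = {}
    for rec in annotations:
        if rec.feature_type in SUBGENE_KINDS:
            sub_trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, rec.id)
        elif rec.feature_type == "gene":
            gene_trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, rec.id)

    seen_loci = set()
    for var in variants:
        key = (var.chrom, var.pos)
        if key in seen_loci:
            continue
        seen_loci.add(key)
        nid = variant_node_id(var.chrom, var.pos)
        kg.add_node(FeatureNode(
            node_id=nid, kind="snp", label=var.id or nid,
            interval=(var.chrom, var.pos, var.pos + 1), combine_rule="leaf",
        ))
        containing = [iv.data for iv in sub_trees.get(var.chrom, IntervalTree())[var.pos]]
        if containing:
            # keep only minimal elements under interval containment
            ivs = {cid: kg.nodes[cid].interval for cid in containing}
            for cid in containing:
                a = ivs[cid]
                minimal = True
                for oid in containing:
                    if oid == cid:
                        continue
                    b = ivs[oid]
                    if (b[1] >= a[1] and b[2] <= a[2]) and (b[1], b[2]) != (a[1], a[2]):
                        minimal = False  # a strictly contains another hit
                        break
                if minimal:
                    kg.add_edge(nid, cid)
        else:
            for iv in gene_trees.get(var.chrom, IntervalTree())[var.pos]:
                kg.add_edge(nid, iv.data)

    kg.check_acyclic()
    return kg


def graft_go(kg: KnowledgeGraph, go_edges: Iterable[tuple[str, str]], associations) -> KnowledgeGraph:
    """Graft the GO DAG(s) onto gene nodes.

    GO term nodes are added with child-term -> parent-term edges.  A GO
    *leaf* term (no child terms) associated with genes present in the
    graph becomes a threshold node fed by those genes (edge gene -> GO
    leaf): information flows bottom-up from gene-level variant counts.
    Internal GO terms combine by OR.  Associations to internal terms or
    to absent genes are skipped with a warning.
    """
    go_edges = list(go_edges)
    associations = list(associations)
    terms = {t for e in go_edges for t in e} | {a.go_term for a in associations}
    sub = nx.DiGraph()
    sub.add_nodes_from(terms)
    sub.add_edges_from(go_edges)
    if not nx.is_directed_acyclic_graph(sub):
        raise ValueError("GO is_a relations contain a cycle")
    go_leaves = {t for t in terms if sub.in_degree(t) == 0}

    for term in sorted(terms):
        kg.add_node(FeatureNode(
            node_id=term, kind="go_term", label=term,
            combine_rule="threshold" if term in go_leaves else "or",
        ))
    for child, parent in go_edges:
        kg.add_edge(child, parent)

    term_genes: dict[str, list[str]] = {}
    for assoc in associations:
        if assoc.go_term not in go_leaves:
            continue
        if assoc.gene_id not in kg.nodes or kg.nodes[assoc.gene_id].kind != "gene":
            warnings.warn(f"association {assoc.gene_id} -> {assoc.go_term}: gene not in graph; skipped")
            continue
        term_genes.setdefault(assoc.go_term, [])
        if assoc.gene_id not in term_genes[assoc.go_term]:
            term_genes[assoc.go_term].append(assoc.gene_id)
            kg.add_edge(assoc.gene_id, assoc.go_term)

    for term, genes in term_genes.items():
        kg.nodes[term].genes = tuple(sorted(genes))

    kg.check_acyclic()
    return kg


def collapse_redundant(kg: KnowledgeGraph) -> KnowledgeGraph:
    """Contract edges whose endpoint vectors are bit-identical.

    The surviving node is always the parent (higher abstraction); the
    alias map records merged id -> survivor.  Iterates in topological
    order until no identical-vector edge remains.  When contraction
    would close a cycle — a node with a different vector sits on an
    alternative path between the endpoints, possible below threshold
    nodes — the direct edge is dropped instead: reachability is already
    carried by the alternative path, so no path-based relation changes.
    """
    out = kg.copy()
    for nid, node in out.nodes.items():
        if node.vector is None:
            raise ValueError(f"node {nid} has no vector; encode before collapsing")

    changed = True
    while changed:
        changed = False
        for u in out.topological_order():
            if u not in out.nodes:
                continue
            for v in out.parents(u):
                if not np.array_equal(out.nodes[u].vector, out.nodes[v].vector):
                    continue
                out._g.remove_edge(u, v)
                if nx.has_path(out._g, u, v):
                    changed = True  # transitively redundant edge dropped
                    break
                for c in list(out.children(u)):
                    if c != v:
                        out._g.add_edge(c, v)
                for p in list(out.parents(u)):
                    if p != v:
                        out._g.add_edge(v, p)
                # merge gene feeds of threshold nodes
                if out.nodes[v].combine_rule == "threshold" or out.nodes[u].combine_rule == "threshold":
                    merged = tuple(sorted(set(out.nodes[u].genes) | set(out.nodes[v].genes)))
                    out.nodes[v].genes = merged
                out.remove_node(u)
                for k, tgt in list(out.alias.items()):
                    if tgt == u:
                        out.alias[k] = v
                out.alias[u] = v
                changed = True
                break

    out.check_acyclic()
    return out
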