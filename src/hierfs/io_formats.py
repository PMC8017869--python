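"""Readers for VCF / GFF3 / OBO / GAF / label files and the graph store.

All genomic coordinates are converted once at this boundary to 0-based
half-open intervals (GFF3 and VCF are 1-based on disk).  The graph store
is a single text container: a node table and edge list as TSV sections
plus one hex-encoded bit vector row per node, in node-table order.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from cyvcf2 import VCF
from gffutils.iterators import DataIterator

from .graph import FeatureNode, KnowledgeGraph

GO_ID_RE = re.compile(r"^GO:\d{7}$")

#: GFF3 type strings -> internal node kinds; configurable dialect map
DEFAULT_TYPE_ALIASES = {
    "gene": "gene",
    "mRNA": "transcript",
    "transcript": "transcript",
    "exon": "exon",
    "five_prime_UTR": "utr",
    "three_prime_UTR": "utr",
    "biological_region": "bio_region",
    "peptide": "peptide",
    "polypeptide": "peptide",
}


@dataclass
class VariantRecord:
    """One VCF record reduced to per-sample variant presence."""

    chrom: str
    pos: int  # 0-based internal coordinate
    id: str
    #: boolean presence per sample, in cohort order: >=1 ALT allele
    presence: np.ndarray


@dataclass
class AnnotationRecord:
    chrom: str
    start: int  # 0-based half-open
    end: int
    feature_type: str
    id: str
    parent_id: Optional[str] = None


@dataclass(frozen=True)
class GoAssociation:
    gene_id: str
    go_term: str

    def __post_init__(self):
        if not GO_ID_RE.match(self.go_term):
            raise ValueError(f"malformed GO id {self.go_term!r}")


class VcfError(ValueError):
    pass


def read_vcf(path, cohort_sample_order: Sequence[str]) -> list[VariantRecord]:
    """Stream VCF records with genotype columns reordered to the cohort.

    Presence means at least one ALT allele (het or hom-alt); missing
    genotypes count as absent.
    """
    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    index = []
    for s in cohort_sample_order:
        if s not in header_samples:
            raise VcfError(f"unknown sample {s!r}: not in VCF header")
        index.append(header_samples.index(s))
    index = np.asarray(index, dtype=int)

    records = []
    for lineno, v in enumerate(vcf, start=1):
        try:
            gt = np.asarray(v.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        except Exception as exc:  # pragma: no cover - malformed htslib record
            raise VcfError(f"malformed VCF record #{lineno}") from exc
        presence = ((gt == 1) | (gt == 3))[index]
        records.append(VariantRecord(
            chrom=v.CHROM, pos=v.POS - 1, id=v.ID or ".", presence=presence,
        ))
    return records


def read_gff3(path, type_aliases: Optional[dict] = None) -> list[AnnotationRecord]:
    """Parse GFF3, keeping only the seven recognized feature kinds.

    Records whose ``Parent`` id never appears are kept as orphans with a
    warning; parent links are resolved from the ``Parent=`` attribute.
    """
    aliases = dict(DEFAULT_TYPE_ALIASES if type_aliases is None else type_aliases)
    records: list[AnnotationRecord] = []
    for feat in DataIterator(str(path)):
        kind = aliases.get(feat.featuretype)
        if kind is None:
            continue
        ids = feat.attributes.get("ID", [])
        fid = ids[0] if ids else f"{feat.featuretype}:{feat.seqid}:{feat.start}-{feat.end}"
        parents = feat.attributes.get("Parent", [])
        records.append(AnnotationRecord(
            chrom=feat.seqid, start=feat.start - 1, end=feat.end,
            feature_type=kind, id=fid,
            parent_id=parents[0] if parents else None,
        ))
    known = {r.id for r in records}
    for r in records:
        if r.parent_id is not None and r.parent_id not in known:
            warnings.warn(f"{r.id}: Parent {r.parent_id!r} never appears; kept as orphan")
    return records


def read_go(obo_path, assoc_path) -> tuple[list[tuple[str, str]], list[GoAssociation]]:
    """Read a GO OBO file plus associations (GAF 2.x or 2-column TSV).

    Returns is_a edges oriented child term -> parent term (obsolete terms
    are dropped by the OBO reader) and the gene/term associations.
    Associations carrying a NOT qualifier are dropped.
    """
    import networkx as nx
    import obonet

    go = obonet.read_obo(str(obo_path))
    edges = sorted(
        (u, v) for u, v, key in go.edges(keys=True) if key == "is_a"
    )
    sub = nx.DiGraph(edges)
    if not nx.is_directed_acyclic_graph(sub):
        raise ValueError("GO is_a relations contain a cycle (DAG violation)")

    associations: list[GoAssociation] = []
    with open(assoc_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) >= 15:  # GAF 2.x
                qualifier = cols[3]
                if "NOT" in qualifier.split("|"):
                    continue
                gene = cols[1] or cols[2]
                term = cols[4]
            elif len(cols) == 2:
                gene, term = cols
            else:
                warnings.warn(f"association line with {len(cols)} columns skipped")
                continue
            if not GO_ID_RE.match(term):
                warnings.warn(f"malformed GO id {term!r} skipped")
                continue
            associations.append(GoAssociation(gene_id=gene, go_term=term))
    return edges, associations


def read_labels(path) -> tuple[list[str], np.ndarray]:
    """Read a 2-column TSV (sample_id, label)."""
    samples, labels = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid, lab = line.split("\t")
            samples.append(sid)
            labels.append(lab)
    arr = np.asarray(labels)
    try:
        arr = arr.astype(int)
    except ValueError:
        pass
    return samples, arr


# ---------------------------------------------------------------------
# graph store: TSV node table + edge list + hex vector rows
# ---------------------------------------------------------------------

def _interval_str(iv) -> str:
    return "." if iv is None else f"{iv[0]}:{iv[1]}-{iv[2]}"


def _parse_interval(s: str):
    if s == ".":
        return None
    chrom, rng = s.rsplit(":", 1)
    a, b = rng.split("-")
    return (chrom, int(a), int(b))


def write_graph(kg: KnowledgeGraph, path, n_samples: Optional[int] = None) -> None:
    """Serialize the graph bit-exactly to the TSV+hex container."""
    node_ids = sorted(kg.nodes)
    if n_samples is None:
        for nid in node_ids:
            if kg.nodes[nid].vector is not None:
                n_samples = int(kg.nodes[nid].vector.size)
                break
        else:
            n_samples = 0
    edges = sorted(kg.edges)
    aliases = sorted(kg.alias.items())
    with open(path, "w") as fh:
        fh.write(f"#hkg\t1\tn_samples={n_samples}\tnodes={len(node_ids)}\t"
                 f"edges={len(edges)}\taliases={len(aliases)}\n")
        fh.write("#nodes\n")
        for nid in node_ids:
            nd = kg.nodes[nid]
            genes = ",".join(nd.genes) if nd.genes else "."
            fh.write(f"{nid}\t{nd.kind}\t{nd.label}\t{_interval_str(nd.interval)}\t"
                     f"{nd.combine_rule}\t{genes}\n")
        fh.write("#edges\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")
        fh.write("#alias\n")
        for k, v in aliases:
            fh.write(f"{k}\t{v}\n")
        fh.write("#vectors\n")
        for nid in node_ids:
            vec = kg.nodes[nid].vector
            if vec is None:
                fh.write(".\n")
            else:
                if vec.size != n_samples:
                    raise ValueError(f"node {nid}: vector length {vec.size} != n_samples {n_samples}")
                fh.write(np.packbits(vec.astype(np.uint8)).tobytes().hex() + "\n")


class GraphStoreError(ValueError):
    pass


def read_graph(path) -> tuple[KnowledgeGraph, int]:
    """Read the graph store; raises :class:`GraphStoreError` on any
    field-count or length mismatch against the header."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#hkg\t"):
        raise GraphStoreError("missing #hkg header")
    head = dict(kv.split("=") for kv in lines[0].split("\t")[2:])
    n_samples = int(head["n_samples"])
    n_nodes, n_edges, n_alias = int(head["nodes"]), int(head["edges"]), int(head["aliases"])

    def section(tag, start):
        if start >= len(lines) or lines[start] != tag:
            raise GraphStoreError(f"expected section {tag}")
        return start + 1

    kg = KnowledgeGraph()
    i = section("#nodes", 1)
    node_ids = []
    for _ in range(n_nodes):
        if i >= len(lines):
            raise GraphStoreError("truncated node table")
        parts = lines[i].split("\t")
        if len(parts) != 6:
            raise GraphStoreError(f"node row has {len(parts)} fields, expected 6")
        nid, kind, label, ivs, rule, genes = parts
        kg.add_node(FeatureNode(
            node_id=nid, kind=kind, label=label, interval=_parse_interval(ivs),
            combine_rule=rule, genes=() if genes == "." else tuple(genes.split(",")),
        ))
        node_ids.append(nid)
        i += 1
    i = section("#edges", i)
    for _ in range(n_edges):
        if i >= len(lines):
            raise GraphStoreError("truncated edge list")
        u, v = lines[i].split("\t")
        kg.add_edge(u, v)
        i += 1
    i = section("#alias", i)
    for _ in range(n_alias):
        if i >= len(lines):
            raise GraphStoreError("truncated alias table")
        k, v = lines[i].split("\t")
        kg.alias[k] = v
        i += 1
    i = section("#vectors", i)
    nbytes = (n_samples + 7) // 8
    for nid in node_ids:
        if i >= len(lines):
            raise GraphStoreError("truncated vector section")
        row = lines[i]
        if row != ".":
            if len(row) != nbytes * 2:
                raise GraphStoreError(f"vector row for {nid} has wrong length")
            bits = np.unpackbits(np.frombuffer(bytes.fromhex(row), dtype=np.uint8))
            kg.nodes[nid].vector = bits[:n_samples].astype(bool)
        i += 1
    return kg, n_samples
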