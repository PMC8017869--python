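"""Per-sample binary vector assignment.

Leaf (SNP) nodes get presence vectors straight from the variant calls;
GO leaf terms get enrichment vectors from the mu+sigma rule over variant
counts in their associated genes; every other node is the bitwise OR of
its children plus any variants mapped directly to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .graph import KnowledgeGraph, variant_node_id


@dataclass
class Cohort:
    """Ordered sample identifiers plus the label vector L."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels and sample_ids differ in length")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: Sequence[str]) -> "Cohort":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return Cohort(sample_ids=list(sample_ids), labels=self.labels[idx])


@dataclass
class GoThresholdStats:
    """Count statistics behind a GO-leaf enrichment vector."""

    counts: np.ndarray
    mu: float
    sigma: float
    cutoff: float  # mu + sigma exactly


def encode_leaves(kg: KnowledgeGraph, variants, cohort: Cohort) -> None:
    """Assign presence vectors to leaf nodes in place.

    Bit i is set when sample i carries at least one non-reference allele
    at a variant mapped to the node; structural leaves with no variants
    get all-zero vectors.
    """
    n = cohort.n
    locus_presence: dict[str, np.ndarray] = {}
    for var in variants:
        if var.presence.size != n:
            raise ValueError(
                f"variant {var.chrom}:{var.pos + 1} has {var.presence.size} genotypes "
                f"for a cohort of {n}; sample order mismatch")
        nid = variant_node_id(var.chrom, var.pos)
        prev = locus_presence.get(nid)
        locus_presence[nid] = var.presence.astype(bool) if prev is None else (prev | var.presence)

    for nid, node in kg.nodes.items():
        if node.kind == "snp":
            node.vector = locus_presence.get(nid, np.zeros(n, dtype=bool)).copy()
        elif not kg.children(nid) and node.combine_rule == "or":
            node.vector = np.zeros(n, dtype=bool)


def go_leaf_threshold(counts: np.ndarray, frozen_cutoff: Optional[float] = None,
                      ) -> tuple[np.ndarray, GoThresholdStats]:
    """Enrichment vector for a GO leaf from per-sample variant counts.

    Bit i is set when counts[i] >= mu + sigma, with mu and sigma the
    mean and population standard deviation of the counts.  A frozen
    cutoff (e.g. computed on training samples) may be supplied instead.
    """
    counts = np.asarray(counts, dtype=float)
    mu = float(counts.mean())
    sigma = float(counts.std())  # population (ddof=0)
    cutoff = mu + sigma if frozen_cutoff is None else float(frozen_cutoff)
    return counts >= cutoff, GoThresholdStats(counts=counts, mu=mu, sigma=sigma, cutoff=cutoff)


def gene_variant_counts(kg: KnowledgeGraph, n: int) -> dict[str, np.ndarray]:
    """Per-gene integer count vectors: distinct variant loci in the
    gene's subtree carried by each sample."""
    counts = {nid: np.zeros(n, dtype=int) for nid, nd in kg.nodes.items() if nd.kind == "gene"}
    snp_sets: dict[str, set[str]] = {g: set() for g in counts}
    for nid, node in kg.nodes.items():
        if node.kind != "snp" or node.vector is None:
            continue
        for anc in kg.ancestors(nid):
            if anc in counts:
                snp_sets[anc].add(nid)
    for g, snps in snp_sets.items():
        for s in sorted(snps):
            counts[g] += kg.nodes[s].vector.astype(int)
    return counts


def _term_counts(kg: KnowledgeGraph, term: str, n: int,
                 gene_snps: dict[str, set[str]]) -> np.ndarray:
    """Distinct variants per sample mapping to ANY gene of the term."""
    loci: set[str] = set()
    for g in kg.nodes[term].genes:
        loci |= gene_snps.get(g, set())
    c = np.zeros(n, dtype=int)
    for s in sorted(loci):
        c += kg.nodes[s].vector.astype(int)
    return c


def propagate_or(kg: KnowledgeGraph, cohort: Cohort,
                 frozen_go_cutoffs: Optional[dict[str, float]] = None,
                 ) -> dict[str, GoThresholdStats]:
    """Assign vectors to all internal nodes in place, bottom-up.

    Threshold (GO leaf) vectors are computed first from gene-level
    variant counts, then OR nodes are filled in topological order:
    vector = OR of children OR'd with any direct leaf contribution.
    Returns the per-term threshold statistics.
    """
    n = cohort.n
    # snp membership per gene subtree (for threshold counts)
    gene_snps: dict[str, set[str]] = {nid: set() for nid, nd in kg.nodes.items() if nd.kind == "gene"}
    for nid, node in kg.nodes.items():
        if node.kind != "snp":
            continue
        if node.vector is None:
            raise ValueError(f"SNP node {nid} has no leaf vector; run encode_leaves first")
        for anc in kg.ancestors(nid):
            if anc in gene_snps:
                gene_snps[anc].add(nid)

    stats: dict[str, GoThresholdStats] = {}
    for nid in sorted(kg.nodes):
        node = kg.nodes[nid]
        if node.combine_rule != "threshold":
            continue
        if not node.genes:
            warnings.warn(f"GO leaf {nid} has no associated genes present; all-zero vector")
            node.vector = np.zeros(n, dtype=bool)
            stats[nid] = GoThresholdStats(np.zeros(n, dtype=int), 0.0, 0.0, 0.0)
            continue
        counts = _term_counts(kg, nid, n, gene_snps)
        frozen = None if frozen_go_cutoffs is None else frozen_go_cutoffs.get(nid)
        node.vector, stats[nid] = go_leaf_threshold(counts, frozen_cutoff=frozen)

    for nid in kg.topological_order():
        node = kg.nodes[nid]
        if node.combine_rule != "or":
            continue
        vec = node.vector if node.vector is not None else np.zeros(n, dtype=bool)
        vec = vec.copy()
        for child in kg.children(nid):
            cvec = kg.nodes[child].vector
            if cvec is None:
                raise ValueError(f"child {child} of {nid} has no vector")
            vec |= cvec
        node.vector = vec
    return stats


def assign_vectors(kg: KnowledgeGraph, variants, cohort: Cohort,
                   frozen_go_cutoffs: Optional[dict[str, float]] = None,
                   ) -> dict[str, GoThresholdStats]:
    """Leaf encoding followed by bottom-up propagation."""
    encode_leaves(kg, variants, cohort)
    return propagate_or(kg, cohort, frozen_go_cutoffs=frozen_go_cutoffs)


def saturation_flags(kg: KnowledgeGraph) -> set[str]:
    """Ids of nodes whose vectors are all ones (zero MI with any label)."""
    out = set()
    for nid, node in kg.nodes.items():
        if node.vector is not None and node.vector.size and node.vector.all():
            out.add(nid)
    return out
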