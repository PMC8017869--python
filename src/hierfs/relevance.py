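"""Feature relevance and redundancy scoring.

Mutual information I(B_i; L) = H(L) - H(L|B_i) measures how much a
binary feature vector tells us about the sample labels; pairwise Pearson
correlation measures redundancy between features.  Only a restricted
candidate pair set enters the downstream ILP penalty: pairs anchored to
a common gene, to overlapping genes, or lying on a directed path.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .encoding import Cohort
from .graph import KnowledgeGraph, _intervals_overlap

DEFAULT_PAIR_GATE = 0.3


def entropy(labels) -> float:
    """Plug-in empirical entropy in bits (0*log 0 := 0)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def conditional_entropy(labels, feature) -> float:
    """H(L | B) = sum_b p(b) H(L | B=b), in bits."""
    labels = np.asarray(labels)
    feature = np.asarray(feature)
    if labels.size != feature.size:
        raise ValueError("label and feature vectors differ in length")
    total = 0.0
    for b in np.unique(feature):
        mask = feature == b
        total += mask.mean() * entropy(labels[mask])
    return float(total)


def mutual_information(feature, labels) -> float:
    """I(B; L) = H(L) - H(L|B), in bits; clipped at 0."""
    return max(entropy(labels) - conditional_entropy(labels, feature), 0.0)


@dataclass
class RelevanceTable:
    """node_id -> I(B_i; L) in bits."""

    mi: dict[str, float]

    def __getitem__(self, node_id: str) -> float:
        return self.mi[node_id]

    def retained(self, t: float) -> set[str]:
        if t < 0:
            raise ValueError("MI threshold must be >= 0")
        return {nid for nid, v in self.mi.items() if v >= t}


def mi_filter(kg: KnowledgeGraph, cohort: Cohort, t: float,
              ) -> tuple[set[str], RelevanceTable]:
    """Score every node and retain those with I(B_i; L) >= t."""
    if t < 0:
        raise ValueError("MI threshold must be >= 0")
    table = {}
    for nid in sorted(kg.nodes):
        vec = kg.nodes[nid].vector
        if vec is None:
            raise ValueError(f"node {nid} has no vector")
        table[nid] = mutual_information(vec, cohort.labels)
    rel = RelevanceTable(mi=table)
    return rel.retained(t), rel


def pearson_binary(x, y) -> float:
    """Pearson correlation of two same-length 0/1 vectors.

    Undefined for a constant vector; defined as 0 with a warning (such
    vectors carry zero MI and are removed by the filter anyway).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors differ in length")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("Pearson correlation of a constant vector; defined as 0")
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


@dataclass(frozen=True)
class CandidatePair:
    i: str  # i < j by id order
    j: str
    corr: float

    @property
    def abs_corr(self) -> float:
        return abs(self.corr)


@dataclass
class CandidatePairSet:
    pairs: dict[tuple[str, str], CandidatePair]

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs.values())

    def keys(self):
        return set(self.pairs)


def gene_anchors(kg: KnowledgeGraph, node_ids=None) -> dict[str, set[str]]:
    """Gene nodes connected to each node by a directed path (either
    direction): the genes a feature's signal is anchored to.

    Structural nodes reach their gene(s) upward; GO terms are reached
    from their genes.  A gene node anchors itself.
    """
    if node_ids is None:
        node_ids = list(kg.nodes)
    genes = [nid for nid, nd in kg.nodes.items() if nd.kind == "gene"]
    anchors = {nid: set() for nid in node_ids}
    reach_from_gene = {g: kg.ancestors(g) for g in genes}
    for nid in node_ids:
        up = kg.ancestors(nid)
        for g in genes:
            if g == nid or g in up or nid in reach_from_gene[g]:
                anchors[nid].add(g)
    return anchors


def build_candidate_pairs(kg: KnowledgeGraph, retained, pair_gate: float = DEFAULT_PAIR_GATE,
                          ) -> CandidatePairSet:
    """Construct the pair set entering the ILP redundancy penalty.

    A retained pair qualifies structurally when the two features share a
    common gene anchor, their gene anchors' intervals overlap, or one is
    reachable from the other along directed edges; it is then kept only
    if |Pearson correlation| >= ``pair_gate``.
    """
    ids = sorted(retained)
    for nid in ids:
        if nid not in kg.nodes:
            raise KeyError(f"retained id {nid!r} not in graph")
    anchors = gene_anchors(kg, ids)
    reach = {nid: kg.ancestors(nid) for nid in ids}
    gene_iv = {nid: kg.nodes[nid].interval for nid in kg.nodes if kg.nodes[nid].kind == "gene"}

    pairs = {}
    for a, b in itertools.combinations(ids, 2):
        structural = bool(anchors[a] & anchors[b]) or (b in reach[a]) or (a in reach[b])
        if not structural:
            for ga in anchors[a]:
                if any(_intervals_overlap(gene_iv[ga], gene_iv[gb]) for gb in anchors[b]):
                    structural = True
                    break
        if not structural:
            continue
        corr = pearson_binary(kg.nodes[a].vector, kg.nodes[b].vector)
        if abs(corr) >= pair_gate:
            pairs[(a, b)] = CandidatePair(i=a, j=b, corr=corr)
    return CandidatePairSet(pairs=pairs)
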