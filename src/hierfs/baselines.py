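"""Comparison selectors: SHSEL-style greedy hierarchical selection and
the plain MI-threshold baseline, plus a redundancy report.

The greedy selector follows the two-step scheme of SHSEL: prune nodes
that are irrelevant or near-duplicates of a direct ancestor while
sweeping leaves-to-root, then keep per root-to-leaf path only the nodes
whose relevance reaches that path's average.  It is a baseline for
parsimony/redundancy comparisons, not a replication of the original
SHSEL code.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import KnowledgeGraph
from .relevance import RelevanceTable, pearson_binary


@dataclass
class ShselConfig:
    similarity_threshold: float = 0.99  # recommended SHSEL setting

    def __post_init__(self):
        if not 0 <= self.similarity_threshold <= 1:
            raise ValueError("similarity threshold must be in [0, 1]")


def _root_leaf_paths(kg: KnowledgeGraph, cap: int = 100_000):
    """All root-to-leaf paths (parent -> child direction)."""
    rev = nx.DiGraph()
    rev.add_nodes_from(kg.nodes)
    for u, v in kg.edges:
        rev.add_edge(v, u)
    paths = []
    for root in kg.roots():
        for leaf in kg.leaves():
            if root == leaf:
                if rev.degree(root) == 0:
                    paths.append([root])
                continue
            for p in nx.all_simple_paths(rev, root, leaf):
                paths.append(p)
                if len(paths) > cap:
                    raise RuntimeError("path enumeration exceeded cap")
    return paths


def shsel_select(kg: KnowledgeGraph, relevance: RelevanceTable,
                 config: ShselConfig | None = None) -> set[str]:
    """Two-step greedy hierarchical selection.

    Step 1 (leaves to root): drop a node whose relevance is 0, or whose
    |Pearson correlation| with any direct parent reaches the similarity
    threshold.  Step 2: a surviving node is kept only if its relevance
    is >= the mean relevance of survivors on at least one root-to-leaf
    path through it.
    """
    config = config or ShselConfig()
    removed: set[str] = set()
    for nid in kg.topological_order():
        if relevance.mi.get(nid, 0.0) == 0.0:
            removed.add(nid)
            continue
        for parent in kg.parents(nid):
            sim = abs(pearson_binary(kg.nodes[nid].vector, kg.nodes[parent].vector))
            if sim >= config.similarity_threshold:
                removed.add(nid)
                break

    survivors = set(kg.nodes) - removed
    keep: set[str] = set()
    for path in _root_leaf_paths(kg):
        on_path = [nid for nid in path if nid in survivors]
        if not on_path:
            continue
        mean = float(np.mean([relevance.mi[nid] for nid in on_path]))
        keep.update(nid for nid in on_path if relevance.mi[nid] >= mean)
    return keep


def threshold_select(relevance: RelevanceTable, t: float) -> set[str]:
    """Plain MI-threshold baseline: every node with I(B_i; L) >= t."""
    return relevance.retained(t)


def redundancy_report(selected, kg: KnowledgeGraph, m: int = 1000,
                      seed: int = 0) -> tuple[float, float]:
    """Mean |pairwise Pearson correlation| over a random sample of the
    selected features, plus its standard error over the sampled pairs."""
    ids = sorted(selected)
    if len(ids) < 2:
        raise ValueError("redundancy report needs at least 2 features")
    rng = np.random.default_rng(seed)
    if len(ids) > m:
        ids = sorted(rng.choice(ids, size=m, replace=False))
    vals = np.array([
        abs(pearson_binary(kg.nodes[a].vector, kg.nodes[b].vector))
        for a, b in itertools.combinations(ids, 2)
    ])
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return float(vals.mean()), se
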