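import itertools

import numpy as np
import pytest

from hierfs.encoding import Cohort
from hierfs.graph import FeatureNode, KnowledgeGraph


def make_node(nid, kind="exon", interval=None, vector=None, rule="or", genes=()):
    return FeatureNode(node_id=nid, kind=kind, label=nid, interval=interval,
                       vector=None if vector is None else np.asarray(vector, dtype=bool),
                       combine_rule=rule, genes=tuple(genes))


def chain_graph(vectors):
    """snp -> exon -> transcript -> gene chain with given vectors."""
    kg = KnowledgeGraph()
    kinds = ["snp", "exon", "transcript", "gene"]
    ids = ["s1", "e1", "t1", "g1"]
    for nid, kind, vec in zip(ids, kinds, vectors):
        kg.add_node(make_node(nid, kind=kind, vector=vec,
                              rule="leaf" if kind == "snp" else "or"))
    for child, parent in zip(ids, ids[1:]):
        kg.add_edge(child, parent)
    return kg


def random_structured_graph(rng, n_samples=12, density=0.5):
    """Random gene/transcript/exon/SNP hierarchy with GO terms on top.

    SNP leaf vectors are random; thresholds and OR nodes are left for
    the encoding stage.  Gene intervals tile one chromosome, with the
    last two genes overlapping half the time to exercise the
    overlapping-anchor pair rule.
    """
    kg = KnowledgeGraph()
    n_genes = int(rng.integers(2, 5))
    pos = 0
    genes = []
    for g in range(n_genes):
        gid = f"g{g}"
        overlap = g == n_genes - 1 and rng.random() < 0.5
        start = pos - 150 if overlap and pos >= 150 else pos
        width = int(rng.integers(300, 600))
        kg.add_node(make_node(gid, kind="gene", interval=("c1", start, start + width)))
        genes.append(gid)
        epos = start
        for t in range(int(rng.integers(1, 3))):
            tid = f"{gid}t{t}"
            kg.add_node(make_node(tid, kind="transcript",
                                  interval=("c1", start, start + width)))
            kg.add_edge(tid, gid)
            for e in range(int(rng.integers(1, 4))):
                eid = f"{tid}e{e}"
                kg.add_node(make_node(eid, kind="exon", interval=("c1", epos, epos + 40)))
                kg.add_edge(eid, tid)
                for s in range(int(rng.integers(0, 3))):
                    sid = f"{eid}s{s}"
                    vec = rng.random(n_samples) < density
                    kg.add_node(make_node(sid, kind="snp", vector=vec, rule="leaf"))
                    kg.add_edge(sid, eid)
                epos += 60
        pos = start + width + 100

    leaf_terms = []
    for k in range(int(rng.integers(1, 4))):
        term = f"GO:{1000 + k:07d}"
        assoc = sorted(rng.choice(genes, size=int(rng.integers(1, len(genes) + 1)),
                                  replace=False).tolist())
        kg.add_node(make_node(term, kind="go_term", rule="threshold", genes=assoc))
        for g in assoc:
            kg.add_edge(g, term)
        leaf_terms.append(term)
    root = "GO:0000001"
    kg.add_node(make_node(root, kind="go_term", rule="or"))
    for term in leaf_terms:
        kg.add_edge(term, root)
    return kg


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_cohort():
    return Cohort(sample_ids=["S1", "S2", "S3", "S4"], labels=np.array([1, 1, 0, 0]))
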