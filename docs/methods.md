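# Methods

## Knowledge-graph construction

The graph G = (V, E) is a DAG over candidate feature encodings; every
edge points child → parent, the parent being the higher abstraction. It
may be disconnected.

**Genomic hierarchy.** One node per annotation record of the seven
recognized kinds (gene, transcript, exon, 5'/3' UTR, peptide,
biological region) and per distinct variant locus. Containment defines
edges: exon → transcript → gene, UTR → transcript (falling back to the
gene when no transcript parent is annotated), and peptide/biological
region → every overlapping gene. A SNP links to every *smallest*
containing sub-gene element (minimal under interval containment; ties
keep both), so that a locus inside nested annotations contributes once
at the most specific level and its ancestors receive the signal through
OR-propagation. A SNP inside a gene but outside all sub-gene elements
links directly to the gene; one overlapping no annotation stays an
isolated leaf. A SNP contained in overlapping elements of two genes
links into both subtrees — containment is the only criterion.
Coordinates are converted once at the I/O boundary to 0-based half-open
intervals; strand is parsed but ignored for containment. The mapping
from GFF3 dialect type strings to the seven kinds is a configurable
alias map (`mRNA`/`transcript` → transcript, `biological_region` → bio
region, `peptide`/`polypeptide` → peptide, ...), since annotation
releases differ in the strings they use for the catch-all categories.

**GO grafting.** GO terms are added with child-term → parent-term
`is_a` edges (the three namespaces remain separate roots; obsolete
terms are dropped at parsing). A GO *leaf* term — no child terms —
associated with genes present in the graph becomes a threshold node fed
by those genes: the edge is oriented gene → GO leaf so that information
flows bottom-up from gene-level variant counts, consistent with every
other edge in the graph. Associations to internal terms are ignored
(only leaves are grafted); associations carrying a NOT qualifier are
dropped; associations to absent genes are skipped with a warning.
Terms with no present gene are retained and produce all-zero vectors.

## Vector assignment

With a cohort of n ordered samples, each SNP leaf gets the presence
vector "≥ 1 ALT allele" (het or hom-alt; a missing genotype `./.`
counts as absent — allele-count dosage is a deliberate non-goal).
GO leaf terms get the enrichment vector: bit i = 1 iff the number of
distinct variant loci in sample i mapping anywhere within the
associated genes' subtrees is ≥ μ + σ, where μ and σ are the mean and
*population* (divide-by-n) standard deviation of those counts across
samples. Population σ is pinned here so tests are exact; it is a
potential divergence point against other implementations of the same
rule. All remaining nodes are OR nodes, filled bottom-up in topological
order: vector = OR of children, OR'd with any variants mapped directly
to the node. Degenerate cases follow the rule literally: identical
counts give σ = 0 and a saturated (all-ones) vector; saturated vectors
carry zero mutual information with any label and fall to the MI filter,
so no special casing is needed.

**Collapsing.** Any edge whose endpoint vectors are bit-identical is
contracted, the parent surviving; the alias map records merged id →
survivor, with alias chains compressed. Iteration runs in topological
order to a fixpoint. One subtlety: after earlier merges, an
identical-vector edge (u, v) can coexist with an alternative directed
path u ⇝ v through a node with a *different* vector (threshold nodes
break the OR-monotonicity that otherwise makes this impossible).
Contracting would close a cycle, so the direct edge is dropped instead:
the alternative path already carries the reachability relation, so no
path-based quantity changes, and both invariants hold — the graph stays
acyclic and no remaining edge joins identical vectors. Collapsing never
changes the set of distinct vectors present.

## Relevance, redundancy, and the candidate pair set

Entropies are plug-in empirical estimates in log base 2 (bits), with
0·log 0 := 0; I(B; L) = H(L) − H(L|B), clipped at zero against float
round-off. Labels may be multi-class; features are binary. The base is
pinned to bits — any fixed base only rescales the t and λ trade-offs.
The pre-filter retains node i iff I(Bᵢ; L) ≥ t.

Pearson correlation on 0/1 vectors is the redundancy measure; for a
constant vector it is undefined and defined here as 0 with a warning
(such vectors have zero MI and are filtered anyway).

The pair set 𝒫 entering the ILP penalty is structural: a retained pair
qualifies when the two features share a common *gene anchor*, when
their gene anchors' genomic intervals overlap, or when one is reachable
from the other along directed edges. A node's gene anchors are the gene
nodes connected to it by a directed path in either direction — the
genes beneath a structural feature, and the genes feeding a GO term.
The either-direction definition keeps pairs of GO terms that share a
gene in 𝒫 even though, with gene → GO edge orientation, neither term
reaches a gene going upward. Qualifying pairs are kept iff
|corr| ≥ 0.3 (the gate is configurable). 𝒫 is evaluated on the
collapsed graph, after filtering.

## The selection ILP

maximize Σ wᵢ·I(Bᵢ;L) − λ·Σ_{(i,j)∈𝒫} z_ij·|Corr(Bᵢ,Bⱼ)| subject to
z_ij ≥ wᵢ + wⱼ − 1, Σ wᵢ ≤ c, all variables binary. With non-negative
penalties the optimum satisfies z_ij = wᵢ·wⱼ; z stays declared binary
for fidelity to the combinatorial statement. λ defaults to 1; c = None
leaves the size unconstrained (the program then chooses its own feature
count). Solved with `scipy.optimize.milp` (HiGHS).

Degenerate optima are resolved deterministically by a second solve over
the optimal face: constrain the objective to within 1e−6 of the found
optimum, then minimize a preference that orders selections by size
first, then by lexicographically smallest sorted id tuple, encoded with
powers of two (exact up to 40 features; beyond that the preference
degrades gracefully while the objective remains optimal). The reported
objective is always recomputed combinatorially from the selected set
with a fixed summation order, so equal selections yield bit-identical
floats. A brute-force enumerator (≤ 20 features) implements the same
(objective, |S|, sorted-tuple) key and serves as the test oracle.
Alternate optima are enumerated by re-solving under no-good cuts
Σ_{i∈S} wᵢ − Σ_{i∉S} wᵢ ≤ |S| − 1 until the objective drops by more
than 1e−9.

## Baselines

The greedy hierarchical baseline follows the two-step SHSEL scheme,
implemented from its published summary rather than the original code:
step 1 sweeps leaves-to-root removing nodes with zero relevance or
|corr| ≥ 0.99 (configurable) with any direct parent; step 2 keeps a
survivor iff its relevance reaches the mean relevance of survivors on
at least one root-to-leaf path through it. Two conventions are ours:
similarity compares against *direct* parents of the input graph, and
step 2 uses at-least-one-path (union) semantics; both are noted as
baseline-fidelity caveats. Relevance is the same MI table the ILP uses,
and all selectors start from the same MI-filtered subgraph, so the
threshold baseline always upper-bounds the SHSEL count by construction.
ReliefF is not re-implemented and no third-party implementation is
available here, so the `relieff-topc` selector raises rather than
approximating. The redundancy report samples up to 1000 selected
features without replacement (seeded) and returns the mean |pairwise
Pearson| with its standard error over sampled pairs.

## Evaluation protocol and leakage contract

Per permutation, a stratified holdout (default 30 %) is set aside and
*everything* cohort-dependent is recomputed from the training samples
only: leaf vectors, GO μ+σ cutoffs, collapsing, MI, correlations, and
the selection itself. Frozen training cutoffs are then applied to the
holdout columns to materialize feature values for scoring. Recomputing
GO thresholds on all samples would leak label-free but cohort-dependent
statistics, so the stricter option is taken; likewise the MI filter is
train-only. Classifiers: logistic regression without regularization
(deterministic), random forest with 100 trees, RBF-kernel SVM; all
other hyperparameters are library defaults, recorded in the run log.
AUC is reported on the untouched holdout; multi-class tasks use
one-vs-rest macro averaging. An empty selection scores 0.5 with a
warning. Fixed seeds reproduce the AUC table bit-identically for
logistic regression.

## Synthetic cohorts

The generator tiles genes along one synthetic chromosome (default 10
genes × 2 transcripts × 3 exons × 2 SNPs per exon, one intronic SNP per
gene, one intergenic SNP, one annotated biological region, and one
overlapping gene pair to exercise the overlap pair rule), with a
miniature three-level GO and leaf-term associations over consecutive
gene windows. Background carriers are i.i.d. at 10 % per locus — a
round value in the common-variant range; there is deliberately no
linkage disequilibrium or demography, so passing tests say nothing
about robustness to correlated background structure. The planted node
(default: the first exon) has its implied vector realized exactly: a
designated SNP carries the planted carrier set (drawn at probability
0.5 for balanced labels) and the node's other SNPs are masked to that
set, so the propagated vector equals the carrier set bit-for-bit.
Labels pass the carrier set through a binary symmetric channel with
flip probability ε (default 0.05, small but non-trivial noise), giving
the planted feature's MI a closed form for oracles. Identical seeds
produce byte-identical files.

The end-to-end harness runs, per cohort, the full leakage-safe pipeline
over ten stratified holdout permutations — the repeated-permutation
protocol the evaluation plan defaults to — and reports per-run holdout
AUC as the mean over permutations, whether the planted node or its
collapse alias was selected in every permutation, and mean selection
sizes per method. At these conditions a single 60-sample holdout makes
AUC ≥ 0.9 a coin-flip-fragile event even for the oracle feature
(ceiling ≈ 0.95 ± 0.028); averaging over the ten permutations measures
the selector rather than one split's label-noise draw.

## Problem sizes and numerical choices

Default test-time sizes: cohorts of 200 samples over ~250-node graphs;
solver/oracle batteries use ≤ 15 features and ≤ 40 pairs per instance
with MI and |corr| drawn on a dyadic 2⁻¹⁰ grid, which makes float sums
exact and exact-equality assertions meaningful. Tie tolerance for
alternate/degenerate optima is 1e−6 (far below the smallest grid
difference); feasibility and objective identities are asserted at
1e−9. The graph store is a plain-text container (TSV node/edge/alias
tables plus one hex-encoded bit-vector row per node) with header counts
serving as a truncation check; round-tripping is bit-exact.

## Known limitations

Phased haplotypes, BCF/tabix, GTF dialects and allele dosage are out of
scope. The SHSEL baseline is a faithful-summary reimplementation, not
the original code. Step-2 path enumeration is exponential in
pathological DAGs (capped, with an error past 100k paths) though
benign on annotation-shaped graphs. The exact tie-break is guaranteed
only up to 40 features; beyond that only optimality of the objective
is guaranteed. GO terms associated with internal ontology nodes are
ignored rather than propagated to descendant leaves.
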