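"""Synthetic cohort generator: toy VCF/GFF3/OBO/GAF/label fixtures.

Genes tile one synthetic chromosome (genes > transcripts > exons, with
5' UTRs, one annotated biological region, and an optional overlapping
gene pair).  Variant carriers are i.i.d. background noise except at a
planted node, whose implied binary vector is realized exactly by forcing
variant presence; labels are that vector passed through a binary
symmetric channel with flip probability epsilon, so the mutual
information of the planted feature has a closed form.

Deliberately unrealistic in population-genetic terms: no linkage
disequilibrium, no demography, and a miniature GO topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .baselines import ShselConfig
from .encoding import Cohort
from .graph import build_genomic_hierarchy, graft_go, variant_node_id
from .ilp import SelectionConfig
from .io_formats import read_gff3, read_go, read_labels, read_vcf

EXON_LEN = 120
INTRON_LEN = 60
UTR_LEN = 30
TRANSCRIPT_GAP = 30
GENE_GAP = 500


@dataclass
class SimSpec:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 200
    n_genes: int = 10
    transcripts_per_gene: int = 2
    exons_per_transcript: int = 3
    snps_per_exon: int = 2
    n_go_terms: int = 5
    genes_per_go_term: int = 3
    #: node ids whose vectors carry the label signal
    planted_nodes: tuple = ("g000.t0.e0",)
    label_noise: float = 0.05  # flip probability epsilon
    background_maf: float = 0.10  # per-SNP carrier probability
    overlapping_gene_pair: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label noise must be in [0, 0.5)")
        if not 0 < self.background_maf < 1:
            raise ValueError("background MAF must be in (0, 1)")
        for f in ("n_samples", "n_genes", "transcripts_per_gene",
                  "exons_per_transcript", "snps_per_exon",
                  "n_go_terms", "genes_per_go_term"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")


@dataclass
class GeneratedData:
    vcf: Path
    gff3: Path
    obo: Path
    gaf: Path
    labels: Path
    truth: dict


def _layout(spec: SimSpec):
    """Annotation rows (GFF3 tuples) and SNP loci (0-based)."""
    chrom = "chr1"
    rows = []  # (type, start0, end0, id, parent)
    exon_snps: dict[str, list[int]] = {}
    gene_snps: dict[str, list[int]] = {}
    pos = 1000
    gene_spans = []
    for g in range(spec.n_genes):
        gid = f"g{g:03d}"
        if spec.overlapping_gene_pair and g == spec.n_genes - 1 and g > 0:
            pos = gene_spans[-1][1] - 200  # overlap the previous gene's tail
        gstart = pos
        intronic = []
        for t in range(spec.transcripts_per_gene):
            tid = f"{gid}.t{t}"
            tstart = pos
            rows.append(("five_prime_UTR", pos, pos + UTR_LEN, f"{tid}.utr5", tid))
            pos += UTR_LEN
            for e in range(spec.exons_per_transcript):
                eid = f"{tid}.e{e}"
                rows.append(("exon", pos, pos + EXON_LEN, eid, tid))
                step = EXON_LEN // (spec.snps_per_exon + 1)
                exon_snps[eid] = [pos + (k + 1) * step for k in range(spec.snps_per_exon)]
                pos += EXON_LEN
                if e < spec.exons_per_transcript - 1:
                    intronic.append(pos + INTRON_LEN // 2)
                    pos += INTRON_LEN
            rows.append(("mRNA", tstart, pos, tid, gid))
            pos += TRANSCRIPT_GAP
        gend = pos
        rows.append(("gene", gstart, gend, gid, None))
        gene_spans.append((gstart, gend))
        gene_snps[gid] = intronic[:1]  # one intronic SNP per gene
        pos = gend + GENE_GAP
    # one biological region over gene 0's first exon neighbourhood
    g0s, _ = gene_spans[0]
    rows.append(("biological_region", g0s + UTR_LEN - 10, g0s + UTR_LEN + EXON_LEN + 10,
                 "bio_0", None))
    intergenic = [pos + 200]  # isolated SNP, inside no annotation
    return chrom, rows, exon_snps, gene_snps, intergenic


def generate(spec: SimSpec, out_dir) -> GeneratedData:
    """Write the five fixture files and return paths plus ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    chrom, rows, exon_snps, gene_snps, intergenic = _layout(spec)

    loci = sorted({p for ps in exon_snps.values() for p in ps}
                  | {p for ps in gene_snps.values() for p in ps}
                  | set(intergenic))
    presence = {p: rng.random(n) < spec.background_maf for p in loci}

    # realize each planted node's vector exactly
    subtree_loci: dict[str, list[int]] = {}
    for eid, ps in exon_snps.items():
        subtree_loci[eid] = list(ps)
        tid, gid = eid.rsplit(".", 1)[0], eid.split(".")[0]
        subtree_loci.setdefault(tid, []).extend(ps)
        subtree_loci.setdefault(gid, []).extend(ps)
    for gid, ps in gene_snps.items():
        subtree_loci.setdefault(gid, []).extend(ps)

    carriers = rng.random(n) < 0.5
    truth_vectors = {}
    for nid in spec.planted_nodes:
        if nid not in subtree_loci:
            raise ValueError(f"planted selector {nid!r} matches no node")
        ps = sorted(set(subtree_loci[nid]))
        presence[ps[0]] = carriers.copy()
        for p in ps[1:]:
            presence[p] = presence[p] & carriers
        truth_vectors[nid] = carriers.copy()

    labels = carriers ^ (rng.random(n) < spec.label_noise)

    # --- VCF ---------------------------------------------------------
    vcf_path = out / "cohort.vcf"
    hom_draw = {p: rng.random(n) < 0.25 for p in loci}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for p in loci:
            gts = ["1/1" if (presence[p][i] and hom_draw[p][i])
                   else "0/1" if presence[p][i] else "0/0" for i in range(n)]
            fh.write(f"{chrom}\t{p + 1}\trs{p + 1}\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")

    # --- GFF3 --------------------------------------------------------
    gff_path = out / "annotation.gff3"
    order = {"gene": 0, "mRNA": 1, "five_prime_UTR": 2, "exon": 2, "biological_region": 0}
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ftype, s0, e0, fid, parent in sorted(rows, key=lambda r: (r[1], order[r[0]], r[3])):
            attrs = f"ID={fid}" + (f";Parent={parent}" if parent else "")
            fh.write(f"{chrom}\tsim\t{ftype}\t{s0 + 1}\t{e0}\t.\t+\t.\t{attrs}\n")

    # --- OBO + associations -----------------------------------------
    obo_path = out / "go.obo"
    terms = [f"GO:{k:07d}" for k in range(1, spec.n_go_terms + 3)]
    root, internal, leaves = terms[0], terms[1], terms[2:]
    with open(obo_path, "w") as fh:
        fh.write("format-version: 1.2\nontology: sim-go\n\n")
        fh.write(f"[Term]\nid: {root}\nname: sim root\nnamespace: biological_process\n\n")
        fh.write(f"[Term]\nid: {internal}\nname: sim internal\n"
                 f"namespace: biological_process\nis_a: {root} ! sim root\n\n")
        for k, term in enumerate(leaves):
            parent = internal if k % 2 == 0 else root
            fh.write(f"[Term]\nid: {term}\nname: sim leaf {k}\n"
                     f"namespace: biological_process\nis_a: {parent} ! parent\n\n")

    gaf_path = out / "associations.tsv"
    with open(gaf_path, "w") as fh:
        for k, term in enumerate(leaves):
            for j in range(spec.genes_per_go_term):
                gid = f"g{(k + j) % spec.n_genes:03d}"
                fh.write(f"{gid}\t{term}\n")

    # --- labels ------------------------------------------------------
    labels_path = out / "labels.tsv"
    with open(labels_path, "w") as fh:
        for s, y in zip(samples, labels.astype(int)):
            fh.write(f"{s}\t{y}\n")

    truth = {
        "planted_nodes": list(spec.planted_nodes),
        "planted_vectors": {k: v.astype(int).tolist() for k, v in truth_vectors.items()},
        "carriers": carriers.astype(int).tolist(),
        "snp_loci": {variant_node_id(chrom, p): None for p in loci},
    }
    return GeneratedData(vcf=vcf_path, gff3=gff_path, obo=obo_path,
                         gaf=gaf_path, labels=labels_path, truth=truth)


def load_generated(data: GeneratedData):
    """Parse the fixture files into pipeline inputs."""
    samples, labels = read_labels(data.labels)
    cohort = Cohort(sample_ids=samples, labels=labels)
    variants = read_vcf(data.vcf, samples)
    annotations = read_gff3(data.gff3)
    go_edges, associations = read_go(data.obo, data.gaf)
    structure = build_genomic_hierarchy(annotations, variants)
    structure = graft_go(structure, go_edges, associations)
    return structure, variants, cohort


@dataclass
class RecoveryReport:
    """Outcome of one end-to-end planted-signal run.

    A run follows the repeated-holdout protocol: selection and model
    building are repeated over stratified train/holdout permutations,
    and the run's AUC is the mean over permutations.
    """

    planted: list[str]
    #: planted node (or its collapse alias) selected in every permutation
    recovered: dict[str, bool]
    selections_ilp: list
    selections_shsel: list
    selections_threshold: list
    auc_ilp: float  # mean holdout AUC over permutations
    auc_shsel: float

    @property
    def all_recovered(self) -> bool:
        return all(self.recovered.values())

    @property
    def n_ilp(self) -> float:
        return float(np.mean([len(s) for s in self.selections_ilp]))

    @property
    def n_shsel(self) -> float:
        return float(np.mean([len(s) for s in self.selections_shsel]))

    @property
    def n_threshold(self) -> float:
        return float(np.mean([len(s) for s in self.selections_threshold]))


def recovery_harness(spec: SimSpec, sel_config: SelectionConfig | None = None,
                     pair_gate: float = 0.3, holdout_fraction: float = 0.30,
                     permutations: int = 10, workdir=None) -> RecoveryReport:
    """Generate a cohort, run the full pipeline leakage-safely, and
    report whether each planted node (or its collapse alias) was
    selected, the per-method selection sizes, and holdout AUCs."""
    import tempfile

    from .evaluation import EvalPlan, evaluate

    sel_config = sel_config or SelectionConfig(lam=1.0, c=None, t=0.1)
    with tempfile.TemporaryDirectory() as tmp:
        wd = Path(workdir) if workdir is not None else Path(tmp)
        data = generate(spec, wd)
        structure, variants, cohort = load_generated(data)
        plan = EvalPlan(holdout_fraction=holdout_fraction,
                        permutations=permutations,
                        classifier="logistic_regression", seed=spec.seed)

        df_ilp, sels_ilp, details = evaluate(
            structure, variants, cohort, "ilp", plan, sel_config=sel_config,
            pair_gate=pair_gate, compute_cv=False, return_details=True)
        df_sh, sels_sh = evaluate(structure, variants, cohort, "shsel", plan,
                                  sel_config=sel_config, compute_cv=False)
        _, sels_th = evaluate(structure, variants, cohort, "threshold", plan,
                              sel_config=sel_config, compute_cv=False)

        recovered = {}
        for nid in spec.planted_nodes:
            recovered[nid] = all(
                det["collapsed"].resolve(nid) in sel
                for det, sel in zip(details, sels_ilp))

    return RecoveryReport(
        planted=list(spec.planted_nodes), recovered=recovered,
        selections_ilp=sels_ilp, selections_shsel=sels_sh,
        selections_threshold=sels_th,
        auc_ilp=float(df_ilp["holdout_auc"].mean()),
        auc_shsel=float(df_sh["holdout_auc"].mean()),
    )
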