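"""End-to-end orchestration: build -> encode -> collapse -> score ->
select -> evaluate, with a run log capturing every parameter and seed so
any output is re-derivable."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baselines import ShselConfig
from .encoding import Cohort, assign_vectors
from .evaluation import EvalPlan, evaluate, select_on_cohort
from .graph import build_genomic_hierarchy, collapse_redundant, graft_go
from .ilp import SelectionConfig
from .io_formats import (read_gff3, read_go, read_labels, read_vcf,
                         write_graph)
from .relevance import build_candidate_pairs, mi_filter

log = logging.getLogger("hierfs")


class PipelineError(RuntimeError):
    """Raised with the failing stage's name."""


@dataclass
class RunConfig:
    vcf: str
    gff3: str
    obo: str
    gaf: str
    labels: str
    out_dir: str
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    plan: EvalPlan = field(default_factory=EvalPlan)
    shsel: ShselConfig = field(default_factory=ShselConfig)
    pair_gate: float = 0.3
    selector: str = "ilp"

    @classmethod
    def from_json(cls, path, **overrides) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sel = SelectionConfig(**raw.pop("selection", {}))
        plan = EvalPlan(**raw.pop("plan", {}))
        shsel = ShselConfig(**raw.pop("shsel", {}))
        return cls(selection=sel, plan=plan, shsel=shsel, **raw)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return wrap


def build_inputs(config: RunConfig):
    samples, labels = _stage("labels")(read_labels, config.labels)
    cohort = Cohort(sample_ids=samples, labels=labels)
    variants = _stage("vcf")(read_vcf, config.vcf, samples)
    annotations = _stage("gff3")(read_gff3, config.gff3)
    go_edges, assoc = _stage("go")(read_go, config.obo, config.gaf)
    structure = _stage("hierarchy")(build_genomic_hierarchy, annotations, variants)
    structure = _stage("graft")(graft_go, structure, go_edges, assoc)
    return structure, variants, cohort


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    structure, variants, cohort = build_inputs(config)
    log.info("graph: %d nodes, %d edges; cohort n=%d",
             len(structure), len(structure.edges), cohort.n)

    encoded = structure.copy()
    _stage("encode")(assign_vectors, encoded, variants, cohort)
    collapsed = _stage("collapse")(collapse_redundant, encoded)
    _stage("serialize")(write_graph, collapsed, out / "graph.hkg", cohort.n)

    retained, table = _stage("score")(mi_filter, collapsed, cohort, config.selection.t)
    pd.DataFrame(sorted(table.mi.items()), columns=["node_id", "mi"]).to_csv(
        out / "scores.tsv", sep="\t", index=False)
    pairs = _stage("pairs")(build_candidate_pairs, collapsed, retained, config.pair_gate)
    pd.DataFrame([(p.i, p.j, p.corr) for p in pairs],
                 columns=["i", "j", "corr"]).to_csv(out / "pairs.tsv", sep="\t", index=False)

    selected, _, _, _ = _stage("select")(
        select_on_cohort, structure, variants, cohort, config.selector,
        config.selection, config.pair_gate, config.shsel)
    pd.DataFrame(
        [(nid, table.mi.get(nid, float("nan")), int(nid in selected))
         for nid in sorted(table.mi)],
        columns=["node_id", "mi", "selected_flag"]).to_csv(
        out / "selected.tsv", sep="\t", index=False)

    auc, _sels = _stage("evaluate")(
        evaluate, structure, variants, cohort, config.selector, config.plan,
        config.selection, config.pair_gate, config.shsel)
    auc.to_csv(out / "auc.tsv", sep="\t", index=False)

    run_log = {
        "hierfs_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": {
            "inputs": {k: str(getattr(config, k)) for k in ("vcf", "gff3", "obo", "gaf", "labels")},
            "selection": asdict(config.selection),
            "plan": asdict(config.plan),
            "shsel": asdict(config.shsel),
            "pair_gate": config.pair_gate,
            "selector": config.selector,
        },
        "graph": {"nodes": len(collapsed), "edges": len(collapsed.edges),
                  "retained": len(retained), "pairs": len(pairs),
                  "selected": len(selected)},
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return out
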