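"""Leakage-safe model building and AUC reporting.

For every train/holdout permutation, everything cohort-dependent —
GO enrichment cutoffs, mutual information, correlations, and the
selection itself — is computed on the training samples only; the frozen
cutoffs are then applied to the holdout columns to materialize feature
values for scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.svm import SVC

from .baselines import ShselConfig, shsel_select, threshold_select
from .encoding import Cohort, assign_vectors
from .graph import KnowledgeGraph, collapse_redundant
from .ilp import FeatureSelectionILP, SelectionConfig, SelectionProblem
from .relevance import build_candidate_pairs, mi_filter

SELECTORS = ("ilp", "shsel", "threshold", "relieff-topc")
CLASSIFIERS = ("logistic_regression", "random_forest_100", "svm_rbf")


@dataclass
class EvalPlan:
    holdout_fraction: float = 0.30
    folds: int = 5
    permutations: int = 10
    classifier: str = "logistic_regression"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")


def split_permutations(cohort: Cohort, plan: EvalPlan) -> list[tuple[list[str], list[str]]]:
    """Stratified holdout splits, one per permutation seed."""
    splits = []
    for p in range(plan.permutations):
        rs = (plan.seed * 100_003 + p) % (2 ** 31)
        train, hold = train_test_split(
            cohort.sample_ids, test_size=plan.holdout_fraction,
            stratify=cohort.labels, random_state=rs)
        train_labels = cohort.subset(train).labels
        if len(np.unique(train_labels)) < len(np.unique(cohort.labels)):
            raise ValueError("a label class is absent from the training split")
        splits.append((list(train), list(hold)))
    return splits


def _make_classifier(name: str, seed: int):
    if name == "logistic_regression":
        # C=inf: plain unregularized maximum-likelihood logistic regression
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    if name == "random_forest_100":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "svm_rbf":
        return SVC(kernel="rbf", probability=False, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def _subset_variants(variants, idx: np.ndarray):
    from .io_formats import VariantRecord
    return [VariantRecord(chrom=v.chrom, pos=v.pos, id=v.id,
                          presence=v.presence[idx]) for v in variants]


def select_on_cohort(structure: KnowledgeGraph, variants, cohort: Cohort,
                     selector: str, sel_config: SelectionConfig,
                     pair_gate: float = 0.3,
                     shsel_config: ShselConfig | None = None):
    """Run encode -> collapse -> MI filter -> selection on one cohort.

    Returns (selected ids, collapsed graph, frozen GO cutoffs, table).
    The MI pre-filter is applied to the collapsed graph for every
    selector, so all methods start from the same retained node set.
    """
    if selector not in SELECTORS:
        raise ValueError(f"unknown selector {selector!r}")
    if selector == "relieff-topc":
        raise NotImplementedError(
            "no ReliefF implementation is available in this environment")
    kg = structure.copy()
    stats = assign_vectors(kg, variants, cohort)
    cutoffs = {nid: s.cutoff for nid, s in stats.items()}
    collapsed = collapse_redundant(kg)
    retained, table = mi_filter(collapsed, cohort, sel_config.t)

    if selector == "threshold":
        return set(retained), collapsed, cutoffs, table

    # induce the filtered subgraph shared by ILP and SHSEL
    filtered = KnowledgeGraph()
    for nid in sorted(retained):
        filtered.add_node(collapsed.nodes[nid])
    for u, v in sorted(collapsed.edges):
        if u in retained and v in retained:
            filtered.add_edge(u, v)

    if selector == "shsel":
        sub_table = table.__class__(mi={nid: table[nid] for nid in retained})
        return shsel_select(filtered, sub_table, shsel_config), collapsed, cutoffs, table

    pairs = build_candidate_pairs(collapsed, retained, pair_gate=pair_gate)
    problem = SelectionProblem(
        mi={nid: table[nid] for nid in retained},
        pairs=list(pairs), config=sel_config)
    result = FeatureSelectionILP(problem).fit()
    return set(result.selected), collapsed, cutoffs, table


def _feature_matrix(structure: KnowledgeGraph, variants, cohort: Cohort,
                    selected, cutoffs) -> np.ndarray:
    kg = structure.copy()
    assign_vectors(kg, variants, cohort, frozen_go_cutoffs=cutoffs)
    return np.column_stack([kg.nodes[nid].vector.astype(float)
                            for nid in sorted(selected)])


def _auc(clf, X_train, y_train, X_hold, y_hold, multiclass: bool) -> float:
    clf.fit(X_train, y_train)
    if multiclass:
        if hasattr(clf, "predict_proba"):
            scores = clf.predict_proba(X_hold)
        else:  # softmax decision values into a probability simplex
            d = clf.decision_function(X_hold)
            e = np.exp(d - d.max(axis=1, keepdims=True))
            scores = e / e.sum(axis=1, keepdims=True)
        return float(roc_auc_score(y_hold, scores, multi_class="ovr", average="macro"))
    if hasattr(clf, "decision_function"):
        scores = clf.decision_function(X_hold)
    else:
        scores = clf.predict_proba(X_hold)[:, 1]
    return float(roc_auc_score(y_hold, scores))


def evaluate(structure: KnowledgeGraph, variants, cohort: Cohort,
             selector: str, plan: EvalPlan,
             sel_config: SelectionConfig | None = None,
             pair_gate: float = 0.3,
             shsel_config: ShselConfig | None = None,
             compute_cv: bool = True, return_details: bool = False):
    """Per-permutation holdout AUC for one selection strategy.

    Returns the AUC table and the per-permutation selected id sets;
    with ``return_details`` also the per-permutation collapsed graphs
    and frozen GO cutoffs.
    """
    sel_config = sel_config or SelectionConfig()
    classes = np.unique(cohort.labels)
    multiclass = len(classes) > 2
    sample_index = {s: k for k, s in enumerate(cohort.sample_ids)}

    rows, selections, details = [], [], []
    for p, (train, hold) in enumerate(split_permutations(cohort, plan)):
        tidx = np.array([sample_index[s] for s in train])
        hidx = np.array([sample_index[s] for s in hold])
        train_cohort = Cohort(sample_ids=list(train), labels=cohort.labels[tidx])
        train_variants = _subset_variants(variants, tidx)

        selected, collapsed, cutoffs, _ = select_on_cohort(
            structure, train_variants, train_cohort, selector,
            sel_config, pair_gate=pair_gate, shsel_config=shsel_config)
        selections.append(set(selected))
        if return_details:
            details.append({"collapsed": collapsed, "cutoffs": cutoffs})

        if not selected:
            warnings.warn(f"permutation {p}: selection is empty; AUC recorded as 0.5")
            rows.append({"permutation": p, "n_selected": 0,
                         "holdout_auc": 0.5, "cv_auc": np.nan})
            continue

        X = _feature_matrix(structure, variants, cohort, selected, cutoffs)
        y = cohort.labels
        clf = _make_classifier(plan.classifier, plan.seed + p)
        auc = _auc(clf, X[tidx], y[tidx], X[hidx], y[hidx], multiclass)
        cv = np.nan
        if compute_cv:
            skf = StratifiedKFold(n_splits=plan.folds, shuffle=True,
                                  random_state=plan.seed + p)
            scoring = "roc_auc_ovr" if multiclass else "roc_auc"
            cv_clf = _make_classifier(plan.classifier, plan.seed + p)
            cv = float(np.mean(cross_val_score(
                cv_clf, X[tidx], y[tidx], cv=skf, scoring=scoring)))
        rows.append({"permutation": p, "n_selected": len(selected),
                     "holdout_auc": auc, "cv_auc": cv})
    if return_details:
        return pd.DataFrame(rows), selections, details
    return pd.DataFrame(rows), selections
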