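"""Optimal feature-subset selection as an integer linear program.

The program selects a subset S of candidate features maximizing

    sum_{i in S} I(B_i; L)  -  lambda * sum_{(i,j) in P, i,j in S} |Corr(B_i, B_j)|

subject to |S| <= c, with binary selection variables w_i and pair
variables z_ij >= w_i + w_j - 1 linearizing the product w_i * w_j.
Solved with the HiGHS mixed-integer backend; degenerate optima are
resolved deterministically (smaller subset first, then lexicographically
smallest sorted id tuple) by a second solve over the optimal face.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

#: objective slack within which two selections count as tied optima
TIE_TOL = 1e-6


@dataclass
class SelectionConfig:
    """Knobs of the selection ILP.

    lam
        relative weight of the redundancy penalty (lambda >= 0).
    c
        maximum number of features; ``None`` leaves the size
        unconstrained (the program then picks its own count).
    t
        MI pre-filter threshold applied upstream.
    """

    lam: float = 1.0
    c: Optional[int] = None
    t: float = 0.0
    time_limit_s: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.c is not None and self.c < 0:
            raise ValueError("c must be >= 0")


@dataclass
class SelectionProblem:
    """Post-filter feature scores, candidate pairs, and configuration."""

    mi: dict[str, float]
    pairs: list  # CandidatePair-like objects with .i, .j, .abs_corr
    config: SelectionConfig = field(default_factory=SelectionConfig)

    def __post_init__(self):
        for p in self.pairs:
            if p.i not in self.mi or p.j not in self.mi:
                raise KeyError(f"pair ({p.i}, {p.j}) endpoint not among features")

    @property
    def ids(self) -> list[str]:
        return sorted(self.mi)

    @property
    def effective_c(self) -> int:
        return len(self.mi) if self.config.c is None else min(self.config.c, len(self.mi))


@dataclass
class SelectionResult:
    """Chosen feature set with its exactly recomputed objective."""

    selected: frozenset
    objective: float
    status: str  # optimal | feasible-time-limit | infeasible
    gap: float = 0.0
    problem: Optional[SelectionProblem] = None

    def summary(self) -> str:
        lines = [
            "Hierarchical feature selection (ILP)",
            f"status: {self.status}    objective: {self.objective:.6f}    "
            f"selected: {len(self.selected)}",
        ]
        if self.problem is not None:
            cfg = self.problem.config
            lines.append(f"features: {len(self.problem.mi)}    pairs: {len(self.problem.pairs)}    "
                         f"lambda: {cfg.lam}    c: {cfg.c if cfg.c is not None else 'unbounded'}")
            lines.append(f"{'feature':<30}{'MI (bits)':>12}  in")
            for nid in self.problem.ids:
                mark = "*" if nid in self.selected else ""
                lines.append(f"{nid:<30}{self.problem.mi[nid]:>12.5f}  {mark}")
        return "\n".join(lines)


def objective_value(selected, problem: SelectionProblem) -> float:
    """Combinatorial objective of a selection (z_ij = w_i * w_j).

    Summation order is fixed (sorted ids, pair list order) so equal
    selections always produce bit-identical floats.
    """
    selected = set(selected)
    unknown = selected - set(problem.mi)
    if unknown:
        raise KeyError(f"unknown feature ids {sorted(unknown)}")
    total = sum(problem.mi[i] for i in problem.ids if i in selected)
    penalty = sum(p.abs_corr for p in problem.pairs if p.i in selected and p.j in selected)
    return total - problem.config.lam * penalty


class FeatureSelectionILP:
    """Model object wrapping one selection problem; ``fit`` solves it."""

    def __init__(self, problem: SelectionProblem):
        self.problem = problem

    @classmethod
    def from_graph(cls, kg, cohort, config: SelectionConfig,
                   pair_gate: float = 0.3) -> "FeatureSelectionILP":
        from .relevance import build_candidate_pairs, mi_filter
        retained, table = mi_filter(kg, cohort, config.t)
        pairs = build_candidate_pairs(kg, retained, pair_gate=pair_gate)
        return cls(SelectionProblem(
            mi={nid: table[nid] for nid in retained},
            pairs=list(pairs), config=config,
        ))

    # -- internal -----------------------------------------------------
    def _solve_milp(self, cost, extra_rows=None, extra_lb=None):
        prob = self.problem
        ids = prob.ids
        nf, npair = len(ids), len(prob.pairs)
        nvar = nf + npair
        idx = {nid: k for k, nid in enumerate(ids)}

        rows, lbs, ubs = [], [], []
        # z_ij >= w_i + w_j - 1   <=>   z - w_i - w_j >= -1
        for k, p in enumerate(prob.pairs):
            row = np.zeros(nvar)
            row[nf + k] = 1.0
            row[idx[p.i]] -= 1.0
            row[idx[p.j]] -= 1.0
            rows.append(row)
            lbs.append(-1.0)
            ubs.append(np.inf)
        # sum w_i <= c
        row = np.zeros(nvar)
        row[:nf] = 1.0
        rows.append(row)
        lbs.append(0.0)
        ubs.append(float(prob.effective_c))
        if extra_rows is not None:
            for r, lb in zip(extra_rows, extra_lb):
                rows.append(r)
                lbs.append(lb)
                ubs.append(np.inf)

        constraints = LinearConstraint(sparse.csr_matrix(np.vstack(rows)), lbs, ubs)
        options = {}
        if prob.config.time_limit_s is not None:
            options["time_limit"] = prob.config.time_limit_s
        res = milp(c=cost, constraints=constraints,
                   integrality=np.ones(nvar), bounds=Bounds(0, 1),
                   options=options)
        return res

    def fit(self, nogood_cuts=None) -> SelectionResult:
        """Two-stage solve: optimal objective, then deterministic
        tie-breaking over selections within TIE_TOL of the optimum."""
        prob = self.problem
        ids = prob.ids
        nf, npair = len(ids), len(prob.pairs)
        if nf == 0:
            return SelectionResult(frozenset(), 0.0, "optimal", problem=prob)

        cuts_rows, cuts_lb = [], []
        if nogood_cuts:
            for sel in nogood_cuts:
                # sum_{i in S} w_i - sum_{i notin S} w_i <= |S| - 1
                row = np.zeros(nf + npair)
                for k, nid in enumerate(ids):
                    row[k] = -1.0 if nid in sel else 1.0
                cuts_rows.append(row)
                cuts_lb.append(1.0 - len(sel))

        mi_vec = np.array([prob.mi[nid] for nid in ids])
        pen_vec = np.array([prob.config.lam * p.abs_corr for p in prob.pairs])
        cost1 = np.concatenate([-mi_vec, pen_vec])  # minimize the negation

        res1 = self._solve_milp(cost1, cuts_rows or None, cuts_lb or None)
        if res1.status == 2 or res1.x is None:
            return SelectionResult(frozenset(), float("-inf"), "infeasible", problem=prob)
        status = "optimal" if res1.status == 0 else "feasible-time-limit"
        best_obj = -float(res1.fun)

        # stage 2: among (near-)optimal selections, prefer fewer features,
        # then the lexicographically smallest sorted id tuple.  Powers of
        # two make the preference exact up to 40 features.
        W = min(nf, 40)
        weights = np.array([2.0 ** (W - min(k, W)) for k in range(nf)])
        big = 2.0 ** (W + 2)
        cost2 = np.concatenate([big - weights, np.zeros(npair)])
        floor_row = np.concatenate([mi_vec, -np.array([prob.config.lam * p.abs_corr
                                                       for p in prob.pairs])])
        rows2 = cuts_rows + [floor_row]
        lbs2 = cuts_lb + [best_obj - TIE_TOL]
        res2 = self._solve_milp(cost2, rows2, lbs2)
        res = res2 if (res2.status == 0 and res2.x is not None) else res1

        w = np.round(res.x[:nf]).astype(int)
        selected = frozenset(nid for k, nid in enumerate(ids) if w[k] == 1)
        gap = float(getattr(res1, "mip_gap", 0.0) or 0.0)
        return SelectionResult(selected=selected,
                               objective=objective_value(selected, prob),
                               status=status, gap=gap, problem=prob)


def build_and_solve(problem: SelectionProblem) -> SelectionResult:
    return FeatureSelectionILP(problem).fit()


def brute_force_select(problem: SelectionProblem) -> SelectionResult:
    """Exhaustive oracle over all subsets with |S| <= c.

    Ties break to the smaller subset, then the lexicographically
    smallest sorted id tuple — the same rule the ILP implements.
    Refuses more than 20 features.
    """
    ids = problem.ids
    if len(ids) > 20:
        raise ValueError("brute force limited to 20 features")
    best_sel, best_obj = frozenset(), objective_value(frozenset(), problem)
    for size in range(1, problem.effective_c + 1):
        for combo in itertools.combinations(ids, size):
            obj = objective_value(combo, problem)
            if obj > best_obj:
                best_obj, best_sel = obj, frozenset(combo)
    return SelectionResult(selected=best_sel, objective=best_obj,
                           status="optimal", problem=problem)


def enumerate_alternate_optima(problem: SelectionProblem, k: int,
                               ) -> list[SelectionResult]:
    """Up to k distinct optima, found by re-solving under no-good cuts.

    Stops as soon as the objective drops below the first optimum (by
    more than 1e-9).
    """
    results: list[SelectionResult] = []
    if k <= 0:
        return results
    model = FeatureSelectionILP(problem)
    first = model.fit()
    if first.status == "infeasible":
        return results
    results.append(first)
    cuts = [first.selected]
    while len(results) < k:
        nxt = model.fit(nogood_cuts=cuts)
        if nxt.status == "infeasible" or nxt.objective < first.objective - 1e-9:
            break
        results.append(nxt)
        cuts.append(nxt.selected)
    return results
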