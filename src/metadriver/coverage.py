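"""Mutually-exclusive coverage selection of K mutations.

Given the binary samples × mutations matrix A with column sums c_j, pairwise
co-occurrence counts c_ij = |{k : a_ki·a_kj = 1}| and M = max_j c_j, the
model selects exactly K columns x ∈ {0,1}^n maximizing

    f(S) = (Σ_{j∈S} c_j) / M  −  (λ/K) · Σ_{i∈S} Σ_{j∈S, j≠i} c_ij / c_i

i.e. normalized coverage minus a co-occurrence (non-exclusivity) penalty
balanced by λ. Three solvers are provided: exhaustive enumeration (globally
optimal, small n), a linearized MILP (HiGHS via scipy), and a greedy
heuristic. All are deterministic, breaking ties toward the lexicographically
smallest selected key set.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from sklearn.base import BaseEstimator, TransformerMixin

from .filtering import MutationKey, MutationMatrix

logger = logging.getLogger(__name__)

_TOL = 1e-9

#: supported readings of the penalty normalization (see CoverageInstance)
PENALTY_MODES = ("lambda_over_K", "lambda_only", "ci_times_K")


class EnumerationBudgetExceeded(RuntimeError):
    """C(n, K) exceeds the enumeration budget; use solve_milp instead."""


@dataclass
class CoverageInstance:
    """Derived quantities of the coverage model for one mutation matrix.

    ``penalty_mode`` selects the normalization of the penalty term; the
    default ``"lambda_over_K"`` divides the pairwise sum by K, keeping both
    objective terms O(1).
    """

    keys: list[MutationKey]
    matrix: np.ndarray  # m × n binary
    K: int
    lambda_cover: float = 1.0
    penalty_mode: str = "lambda_over_K"
    c: np.ndarray = field(init=False)
    C: np.ndarray = field(init=False)  # pairwise co-occurrence, zero diagonal
    M: int = field(init=False)

    def __post_init__(self) -> None:
        if self.K < 1 or self.K > len(self.keys):
            raise ValueError("K must satisfy 1 <= K <= n")
        if self.lambda_cover < 0:
            raise ValueError("lambda_cover must be nonnegative")
        if self.penalty_mode not in PENALTY_MODES:
            raise ValueError(f"penalty_mode must be one of {PENALTY_MODES}")
        a = np.asarray(self.matrix, dtype=np.int64)
        self.c = a.sum(axis=0)
        if (self.c == 0).any():
            raise ValueError("all-zero columns must be removed before solving")
        self.C = a.T @ a
        np.fill_diagonal(self.C, 0)
        self.M = int(self.c.max())

    @classmethod
    def from_matrix(
        cls,
        mm: MutationMatrix,
        K: int,
        lambda_cover: float = 1.0,
        penalty_mode: str = "lambda_over_K",
    ) -> "CoverageInstance":
        return cls(list(mm.mutations), mm.values, K, lambda_cover, penalty_mode)

    @property
    def n(self) -> int:
        return len(self.keys)

    def penalty_coefficient(self, i: int, j: int) -> float:
        """Objective cost of jointly selecting columns i and j (i ≠ j)."""
        lam, K = self.lambda_cover, self.K
        if self.penalty_mode == "lambda_over_K":
            return lam / K * (self.C[i, j] / self.c[i] + self.C[i, j] / self.c[j])
        if self.penalty_mode == "lambda_only":
            return lam * (self.C[i, j] / self.c[i] + self.C[i, j] / self.c[j])
        # "ci_times_K": denominator c_i · K
        return lam * (self.C[i, j] / (self.c[i] * K) + self.C[i, j] / (self.c[j] * K))


@dataclass
class CoverageSolution:
    selected: tuple[MutationKey, ...]
    objective: float
    coverage_fraction: float
    solver: str
    uncovered_rows: int = 0


def objective_value(inst: CoverageInstance, selection) -> float:
    """Evaluate the coverage objective on a K-subset of columns.

    *selection* is a set of column indices or mutation keys of size K.
    """
    idx = _as_indices(inst, selection)
    if len(idx) != inst.K:
        raise ValueError(f"selection size {len(idx)} != K={inst.K}")
    cover = inst.c[idx].sum() / inst.M
    penalty = 0.0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            penalty += inst.penalty_coefficient(idx[a], idx[b])
    return float(cover - penalty)


def _as_indices(inst: CoverageInstance, selection) -> list[int]:
    idx = []
    for s in selection:
        idx.append(s if isinstance(s, (int, np.integer)) else inst.keys.index(s))
    return sorted(set(int(i) for i in idx))


def _coverage_fraction(inst: CoverageInstance, idx: list[int]) -> tuple[float, int]:
    covered = np.asarray(inst.matrix)[:, idx].sum(axis=1) > 0
    coverable = np.asarray(inst.matrix).sum(axis=1) > 0
    n_uncoverable = int((~coverable).sum())
    if n_uncoverable:
        logger.warning("%d all-zero rows excluded from coverage denominator", n_uncoverable)
    denom = int(coverable.sum())
    return float(covered[coverable].sum() / denom) if denom else 0.0, n_uncoverable


def _solution(inst: CoverageInstance, idx: list[int], solver: str) -> CoverageSolution:
    frac, unc = _coverage_fraction(inst, idx)
    keys = tuple(sorted(inst.keys[i] for i in idx))
    return CoverageSolution(keys, objective_value(inst, idx), frac, solver, unc)


def solve_exact(inst: CoverageInstance, budget: int = 10**6) -> CoverageSolution:
    """Globally optimal K-subset by exhaustive enumeration.

    Column order follows the canonical (sorted) key order, so the first
    optimum encountered is the lexicographically smallest optimal key set.
    """
    if math.comb(inst.n, inst.K) > budget:
        raise EnumerationBudgetExceeded(
            f"C({inst.n},{inst.K}) exceeds budget {budget}; use solve_milp"
        )
    order = sorted(range(inst.n), key=lambda j: inst.keys[j])
    best_idx, best_obj = None, -np.inf
    for combo in itertools.combinations(order, inst.K):
        obj = objective_value(inst, combo)
        if obj > best_obj + _TOL:
            best_idx, best_obj = list(combo), obj
    return _solution(inst, best_idx, "exact")


def _milp_once(inst: CoverageInstance, fixed: dict[int, int]) -> tuple[np.ndarray, float]:
    """One HiGHS solve of the linearized model with some x variables fixed."""
    n = inst.n
    pairs = [
        (i, j) for i in range(n) for j in range(i + 1, n) if inst.C[i, j] > 0
    ]
    nvar = n + len(pairs)
    cost = np.zeros(nvar)
    cost[:n] = -(inst.c / inst.M)  # milp minimizes
    for e, (i, j) in enumerate(pairs):
        cost[n + e] = inst.penalty_coefficient(i, j)

    constraints = []
    a_card = np.zeros((1, nvar))
    a_card[0, :n] = 1.0
    constraints.append(LinearConstraint(a_card, inst.K, inst.K))
    if pairs:
        rows, lo, hi = [], [], []
        for e, (i, j) in enumerate(pairs):
            # u >= x_i + x_j - 1  and  u <= x_i, u <= x_j
            r = np.zeros(nvar); r[i] = 1; r[j] = 1; r[n + e] = -1
            rows.append(r); lo.append(-np.inf); hi.append(1.0)
            r = np.zeros(nvar); r[n + e] = 1; r[i] = -1
            rows.append(r); lo.append(-np.inf); hi.append(0.0)
            r = np.zeros(nvar); r[n + e] = 1; r[j] = -1
            rows.append(r); lo.append(-np.inf); hi.append(0.0)
        constraints.append(LinearConstraint(np.array(rows), lo, hi))

    lb = np.zeros(nvar)
    ub = np.ones(nvar)
    for j, v in fixed.items():
        lb[j] = ub[j] = v
    res = milp(
        c=cost,
        constraints=constraints,
        bounds=Bounds(lb, ub),
        integrality=np.ones(nvar),
    )
    if not res.success:
        raise RuntimeError(f"MILP failed: {res.message}")
    return res.x[:n], -res.fun


def solve_milp(inst: CoverageInstance, tie_break: bool = True) -> CoverageSolution:
    """Optimal K-subset via the linearized mixed-integer program.

    The quadratic x_i·x_j penalty terms are linearized with auxiliary
    binaries u_ij (u ≥ x_i + x_j − 1, u ≤ x_i, u ≤ x_j). With *tie_break*
    the lexicographically smallest optimal key set is recovered by
    iteratively fixing variables in canonical key order subject to an
    optimality floor; without it, a single solve is performed.
    """
    x, best = _milp_once(inst, {})
    if tie_break:
        order = sorted(range(inst.n), key=lambda j: inst.keys[j])
        fixed: dict[int, int] = {}
        n_ones = 0
        for j in order:
            if n_ones == inst.K:
                fixed[j] = 0
                continue
            trial = dict(fixed); trial[j] = 1
            try:
                _, obj = _milp_once(inst, trial)
            except RuntimeError:
                obj = -np.inf
            if obj >= best - _TOL:
                fixed[j] = 1
                n_ones += 1
            else:
                fixed[j] = 0
        idx = [j for j, v in fixed.items() if v == 1]
    else:
        idx = [j for j in range(inst.n) if x[j] > 0.5]
    return _solution(inst, sorted(idx), "milp")


def solve_greedy(inst: CoverageInstance) -> CoverageSolution:
    """Greedy heuristic: add the column maximizing the partial objective.

    The partial objective uses the same λ/K normalization as the full
    objective; ties break toward the lexicographically smaller key.
    """
    order = sorted(range(inst.n), key=lambda j: inst.keys[j])
    chosen: list[int] = []
    for _ in range(inst.K):
        best_j, best_val = None, -np.inf
        for j in order:
            if j in chosen:
                continue
            trial = chosen + [j]
            cover = inst.c[trial].sum() / inst.M
            pen = sum(
                inst.penalty_coefficient(a, b)
                for ai, a in enumerate(trial)
                for b in trial[ai + 1:]
            )
            val = cover - pen
            if val > best_val + _TOL:
                best_j, best_val = j, val
        chosen.append(best_j)
    return _solution(inst, sorted(chosen), "greedy")


def choose_K(
    mm: MutationMatrix,
    lambda_cover: float = 1.0,
    penalty_mode: str = "lambda_over_K",
    budget: int = 10**6,
) -> int:
    """Smallest K whose solution covers every coverable sample.

    Sweeps K = 1..n, solving exactly when the enumeration budget allows and
    greedily otherwise; returns the first K attaining full coverage of the
    rows that carry at least one mutation, or the smallest K attaining the
    maximum coverage reached over the sweep.
    """
    n = len(mm.mutations)
    best_frac, best_k = -1.0, 1
    for K in range(1, n + 1):
        inst = CoverageInstance.from_matrix(mm, K, lambda_cover, penalty_mode)
        try:
            sol = solve_exact(inst, budget=budget)
        except EnumerationBudgetExceeded:
            sol = solve_greedy(inst)
        if sol.coverage_fraction >= 1.0 - _TOL:
            return K
        if sol.coverage_fraction > best_frac + _TOL:
            best_frac, best_k = sol.coverage_fraction, K
    return best_k


def solve(
    inst: CoverageInstance, solver: str = "auto", budget: int = 10**6
) -> CoverageSolution:
    """Dispatch to exact / milp / greedy; ``auto`` prefers exact, then MILP."""
    if solver == "auto":
        try:
            return solve_exact(inst, budget=budget)
        except EnumerationBudgetExceeded:
            return solve_milp(inst)
    if solver == "exact":
        return solve_exact(inst, budget=budget)
    if solver == "milp":
        return solve_milp(inst)
    if solver == "greedy":
        return solve_greedy(inst)
    raise ValueError(f"unknown solver {solver!r}")


class ExclusiveCoverSelector(BaseEstimator, TransformerMixin):
    """Scikit-learn style selector of K mutually-exclusive covering columns.

    ``fit(X)`` expects a binary samples × mutations array (or a
    :class:`MutationMatrix`). With ``k=None`` the smallest K attaining full
    coverage is chosen automatically.

    Attributes
    ----------
    k_ : the K actually used
    support_ : boolean column mask of the selected mutations
    selected_keys_ : selected column keys (labels when given, indices otherwise)
    objective_, coverage_fraction_ : solution quality
    """

    def __init__(
        self,
        k: int | None = None,
        lambda_cover: float = 1.0,
        solver: str = "auto",
        penalty_mode: str = "lambda_over_K",
        budget: int = 10**6,
    ):
        self.k = k
        self.lambda_cover = lambda_cover
        self.solver = solver
        self.penalty_mode = penalty_mode
        self.budget = budget

    def _to_matrix(self, X) -> MutationMatrix:
        if isinstance(X, MutationMatrix):
            return X
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        samples = [f"s{i}" for i in range(X.shape[0])]
        keys = [("col", f"{j:06d}") for j in range(X.shape[1])]
        return MutationMatrix(samples, keys, X)

    def fit(self, X, y=None):
        mm = self._to_matrix(X)
        k = self.k if self.k is not None else choose_K(
            mm, self.lambda_cover, self.penalty_mode, self.budget
        )
        inst = CoverageInstance.from_matrix(mm, k, self.lambda_cover, self.penalty_mode)
        sol = solve(inst, solver=self.solver, budget=self.budget)
        self.k_ = k
        self.solution_ = sol
        self.selected_keys_ = sol.selected
        self.objective_ = sol.objective
        self.coverage_fraction_ = sol.coverage_fraction
        self.support_ = np.array([key in set(sol.selected) for key in mm.mutations])
        return self

    def get_support(self):
        return self.support_

    def transform(self, X):
        mm = self._to_matrix(X)
        return mm.values[:, self.support_]
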