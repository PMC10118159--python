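"""Budget-constrained optimal allocation of subjects to condition combinations.

Each allowed combination ``c`` costs ``C_sc = C_s + sum of per-condition
costs`` per subject; the design space Omega is the set of nonnegative
integer allocations whose total cost does not exceed the budget ``B``.
Closed-form optima do not exist, so the optimum is found by exhaustive
enumeration of Omega: the per-combination information matrices are
precomputed once, and each candidate allocation is scored through a
vectorized closed-form inverse of its summed 3x3 information matrix.
Scenario 2 at realistic budgets involves several million candidate
triples and completes in seconds this way.

Baselines: the uniform allocation assigns the largest equal integer
count per combination that fits the budget; the complete design enrols
``floor(B / C_s012)`` subjects, each receiving all three conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from . import model
from .criteria import TIE_RTOL, CriterionSpec, criterion_value
from .errors import InfeasibleDesignError
from .model import (
    COMPLETE,
    PLACEBO_T1,
    PLACEBO_T2,
    T1_T2,
    Combination,
    CovarianceSpec,
)

__all__ = [
    "CostSpec",
    "DesignScenario",
    "Allocation",
    "OptimizationResult",
    "SCENARIO_1",
    "SCENARIO_2",
    "COMPLETE_DESIGN",
    "scenario_by_name",
    "combination_cost",
    "enumerate_feasible",
    "count_feasible",
    "optimize_allocation",
    "uniform_allocation",
    "complete_design_size",
    "complete_allocation",
    "allocation_criterion",
    "evaluate_grid",
]

#: Absolute tolerance, in currency units, for budget comparisons.  Costs
#: are decimal-valued (e.g. 923.6) and optima may sit within cents of the
#: budget, so the comparison must not be corrupted by binary rounding.
BUDGET_ATOL = 1e-6


@dataclass(frozen=True)
class CostSpec:
    """Overhead and per-condition costs plus the total budget.

    ``overhead`` (C_s) is charged once per subject regardless of the
    conditions received; ``per_condition`` holds (C_0, C_1, C_2).
    """

    overhead: float
    per_condition: tuple[float, float, float]
    budget: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "overhead", float(self.overhead))
        per = tuple(float(c) for c in self.per_condition)
        object.__setattr__(self, "per_condition", per)
        object.__setattr__(self, "budget", float(self.budget))
        if self.overhead < 0 or any(c < 0 for c in per):
            raise ValueError("costs must be nonnegative")
        if len(per) != 3:
            raise ValueError("need per-condition costs for conditions 0, 1, 2")
        if not self.budget > 0:
            raise ValueError("budget must be strictly positive")

    def combination_cost(self, combo: Combination) -> float:
        return combination_cost(self, combo)


def combination_cost(costs: CostSpec, combo: Combination) -> float:
    """Per-subject cost ``C_sc = C_s + sum_{i in c} C_i`` of a combination."""
    return costs.overhead + sum(costs.per_condition[i] for i in combo)


@dataclass(frozen=True)
class DesignScenario:
    """The set of condition combinations the trial allows.

    Presets: scenario 1 allows placebo+treatment1 and placebo+treatment2;
    scenario 2 additionally allows treatment1+treatment2; the complete
    design has the single triple combination.
    """

    combinations: tuple[Combination, ...]
    name: str = ""

    def __post_init__(self) -> None:
        combos = tuple(self.combinations)
        object.__setattr__(self, "combinations", combos)
        if not combos:
            raise ValueError("a design scenario needs at least one combination")
        if len(set(combos)) != len(combos):
            raise ValueError("scenario combinations must be distinct")


SCENARIO_1 = DesignScenario((PLACEBO_T1, PLACEBO_T2), name="scenario1")
SCENARIO_2 = DesignScenario((PLACEBO_T1, PLACEBO_T2, T1_T2), name="scenario2")
COMPLETE_DESIGN = DesignScenario((COMPLETE,), name="complete")

_SCENARIOS = {
    "1": SCENARIO_1,
    "scenario1": SCENARIO_1,
    "2": SCENARIO_2,
    "scenario2": SCENARIO_2,
    "complete": COMPLETE_DESIGN,
}


def scenario_by_name(name: str) -> DesignScenario:
    """Resolve ``'1'``, ``'2'`` or ``'complete'`` to a scenario preset."""
    try:
        return _SCENARIOS[str(name).lower()]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; expected '1', '2' or 'complete'"
        ) from None


@dataclass(frozen=True)
class Allocation:
    """Integer subject counts per combination, with the implied totals."""

    counts: Mapping[Combination, int]
    total_cost: float

    def __post_init__(self) -> None:
        counts = {c: int(n) for c, n in self.counts.items()}
        if any(n < 0 for n in counts.values()):
            raise ValueError("allocation counts must be nonnegative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "total_cost", float(self.total_cost))

    @classmethod
    def from_counts(
        cls, costs: CostSpec, counts: Mapping[Combination, int]
    ) -> "Allocation":
        total = sum(int(n) * combination_cost(costs, c) for c, n in counts.items())
        return cls(counts=dict(counts), total_cost=total)

    @property
    def total_n(self) -> int:
        return sum(self.counts.values())

    def count(self, combo: Combination) -> int:
        return int(self.counts.get(combo, 0))

    def count_vector(self, combos: Sequence[Combination]) -> tuple[int, ...]:
        return tuple(self.count(c) for c in combos)

    def as_dict(self) -> dict[str, int]:
        return {f"N{c.label}": n for c, n in self.counts.items()}


@dataclass
class OptimizationResult:
    """Outcome of an exhaustive search over the design space."""

    optimal: Allocation
    criterion: CriterionSpec
    criterion_value: float
    n_evaluated: int
    ties: list[Allocation] = field(default_factory=list)


def _max_count(budget: float, unit_cost: float) -> int:
    return int(math.floor((budget + BUDGET_ATOL) / unit_cost))


def enumerate_feasible(
    costs: CostSpec, scenario: DesignScenario
) -> Iterator[Allocation]:
    """Yield every integer allocation whose total cost fits the budget.

    Includes boundary allocations with zero counts (and the all-zero
    allocation).  The enumeration is lexicographic in the scenario's
    combination order.
    """
    combos = scenario.combinations
    unit_costs = [combination_cost(costs, c) for c in combos]
    for combo, uc in zip(combos, unit_costs):
        if uc <= 0:
            raise InfeasibleDesignError(
                f"combination {combo.label} has nonpositive cost {uc}: "
                "the design space would be infinite"
            )

    def rec(i: int, prefix: tuple[int, ...], remaining: float):
        if i == len(combos):
            counts = dict(zip(combos, prefix))
            yield Allocation(counts=counts, total_cost=costs.budget - remaining)
            return
        for n in range(_max_count(remaining, unit_costs[i]) + 1):
            yield from rec(i + 1, prefix + (n,), remaining - n * unit_costs[i])

    yield from rec(0, (), costs.budget)


def count_feasible(costs: CostSpec, scenario: DesignScenario) -> int:
    """Size of the design space Omega (number of feasible allocations)."""
    combos = scenario.combinations
    unit_costs = [combination_cost(costs, c) for c in combos]

    def rec(i: int, remaining: float) -> int:
        if i == len(combos):
            return 1
        total = 0
        for n in range(_max_count(remaining, unit_costs[i]) + 1):
            total += rec(i + 1, remaining - n * unit_costs[i])
        return total

    return rec(0, costs.budget)


# ---------------------------------------------------------------------------
# Vectorized enumeration kernel


def _count_batches(
    unit_costs: Sequence[float], budget: float
) -> Iterator[np.ndarray]:
    """Yield (n_points, k) integer arrays covering Omega exactly once.

    The trailing two dimensions are fully vectorized; any leading
    dimensions are looped scalar.  Order is lexicographic in the
    combination order.
    """
    k = len(unit_costs)
    if k == 1:
        n = np.arange(_max_count(budget, unit_costs[0]) + 1, dtype=np.int64)
        yield n[:, None]
        return

    def last_two(prefix: tuple[int, ...], remaining: float) -> np.ndarray:
        cb, cc = unit_costs[-2], unit_costs[-1]
        bmax = _max_count(remaining, cb)
        b = np.arange(bmax + 1, dtype=np.int64)
        cmax = np.floor((remaining - b * cb + BUDGET_ATOL) / cc).astype(np.int64)
        sizes = cmax + 1
        total = int(sizes.sum())
        starts = np.cumsum(sizes) - sizes
        b_col = np.repeat(b, sizes)
        c_col = np.arange(total, dtype=np.int64) - np.repeat(starts, sizes)
        cols = [np.full(total, p, dtype=np.int64) for p in prefix]
        return np.column_stack(cols + [b_col, c_col])

    def rec(prefix: tuple[int, ...], remaining: float) -> Iterator[np.ndarray]:
        if len(prefix) == k - 2:
            yield last_two(prefix, remaining)
            return
        uc = unit_costs[len(prefix)]
        for n in range(_max_count(remaining, uc) + 1):
            yield from rec(prefix + (n,), remaining - n * uc)

    yield from rec((), budget)


def _batch_phis(
    counts: np.ndarray,
    combos: Sequence[Combination],
    infos: Sequence[np.ndarray],
    pair_variance: Mapping[int, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contrast variances and D_A value for a batch of candidate counts.

    Returns ``(phi01, phi02, phi_da)`` arrays with ``inf`` wherever the
    corresponding quantity is not estimable.  The summed information
    matrix has full rank iff every condition is informed (for the valid
    combination sets any two distinct combinations jointly cover all
    three conditions), so the closed-form symmetric 3x3 inverse applies
    on that mask; single-pair supports fall back to the paired-difference
    closed form ``(sigma_0^2 + sigma_i^2 - 2 sigma_0i) / n``.
    """
    npts = counts.shape[0]
    phi01 = np.full(npts, np.inf)
    phi02 = np.full(npts, np.inf)
    phida = np.full(npts, np.inf)

    informed = np.zeros((npts, 3), dtype=bool)
    for j, combo in enumerate(combos):
        pos = counts[:, j] > 0
        for cond in combo:
            informed[:, cond] |= pos
    full = informed.all(axis=1)

    if np.any(full):
        cf = counts[full].astype(float)
        # six distinct entries of the symmetric summed information matrix
        m = {}
        for (r, s) in ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)):
            entry = np.zeros(cf.shape[0])
            for j, I in enumerate(infos):
                if I[r, s] != 0.0:
                    entry += cf[:, j] * I[r, s]
            m[(r, s)] = entry
        n00 = m[(1, 1)] * m[(2, 2)] - m[(1, 2)] ** 2
        n01 = m[(0, 2)] * m[(1, 2)] - m[(0, 1)] * m[(2, 2)]
        n02 = m[(0, 1)] * m[(1, 2)] - m[(0, 2)] * m[(1, 1)]
        n11 = m[(0, 0)] * m[(2, 2)] - m[(0, 2)] ** 2
        n12 = m[(0, 1)] * m[(0, 2)] - m[(0, 0)] * m[(1, 2)]
        n22 = m[(0, 0)] * m[(1, 1)] - m[(0, 1)] ** 2
        det = m[(0, 0)] * n00 + m[(0, 1)] * n01 + m[(0, 2)] * n02
        p01 = (n00 + n11 - 2.0 * n01) / det
        p02 = (n00 + n22 - 2.0 * n02) / det
        cross = (n00 + n12 - n01 - n02) / det
        phi01[full] = p01
        phi02[full] = p02
        phida[full] = p01 * p02 - cross**2

    # single-pair supports: only one combination positive and it is a
    # placebo-treatment pair -> that contrast alone is estimable
    for j, combo in enumerate(combos):
        if len(combo) != 2 or 0 not in combo:
            continue
        treatment = combo.conditions[1]
        only = counts[:, j] > 0
        for jj in range(len(combos)):
            if jj != j:
                only &= counts[:, jj] == 0
        only &= ~full
        if np.any(only):
            vals = pair_variance[treatment] / counts[only, j].astype(float)
            if treatment == 1:
                phi01[only] = vals
            else:
                phi02[only] = vals

    return phi01, phi02, phida


def _pair_variances(cov: CovarianceSpec) -> dict[int, float]:
    """Closed-form contrast variance per subject for each placebo pair."""
    v = cov.variances
    s01, s02, _ = cov.covariances
    return {1: v[0] + v[1] - 2.0 * s01, 2: v[0] + v[2] - 2.0 * s02}


def _criterion_from_phis(
    criterion: CriterionSpec,
    phi01: np.ndarray,
    phi02: np.ndarray,
    phida: np.ndarray,
) -> np.ndarray:
    if criterion.kind == "DA":
        return phida
    lam = criterion.lambda1
    if lam == 1.0:  # zero weight on the second contrast: 0 x inf := 0
        return phi01
    if lam == 0.0:
        return phi02
    return lam * phi01 + (1.0 - lam) * phi02


def optimize_allocation(
    costs: CostSpec,
    cov: CovarianceSpec,
    scenario: DesignScenario,
    criterion: CriterionSpec,
) -> OptimizationResult:
    """Exhaustively search Omega for the criterion-minimizing allocation.

    Allocations with an infinite criterion value (a contrast with
    nonzero weight left non-estimable) are skipped.  Ties within a
    relative tolerance of ``TIE_RTOL`` are broken by lower total cost,
    then by lexicographically smaller counts in combination order; all
    tied allocations are reported.
    """
    combos = scenario.combinations
    unit_costs = np.array([combination_cost(costs, c) for c in combos])
    for combo, uc in zip(combos, unit_costs):
        if uc <= 0:
            raise InfeasibleDesignError(
                f"combination {combo.label} has nonpositive cost {uc}: "
                "the design space would be infinite"
            )
    D = cov.matrix()
    infos = [model.combination_information(D, c) for c in combos]
    pair_var = _pair_variances(cov)

    n_evaluated = 0
    best = np.inf
    # candidate tuples: (value, cost, counts)
    candidates: list[tuple[float, float, tuple[int, ...]]] = []

    for batch in _count_batches(unit_costs, costs.budget):
        n_evaluated += batch.shape[0]
        phi01, phi02, phida = _batch_phis(batch, combos, infos, pair_var)
        vals = _criterion_from_phis(criterion, phi01, phi02, phida)
        finite = np.isfinite(vals)
        if not np.any(finite):
            continue
        bmin = float(vals[finite].min())
        if bmin < best:
            best = bmin
        keep = finite & (vals <= best * (1.0 + TIE_RTOL))
        if np.any(keep):
            kept_counts = batch[keep]
            kept_vals = vals[keep]
            kept_costs = kept_counts.astype(float) @ unit_costs
            for v, c, row in zip(kept_vals, kept_costs, kept_counts):
                candidates.append((float(v), float(c), tuple(int(x) for x in row)))
            # keep the candidate list from growing without bound
            if len(candidates) > 4096:
                candidates = [
                    t for t in candidates if t[0] <= best * (1.0 + TIE_RTOL)
                ]

    if not math.isfinite(best):
        offending = (
            "both placebo-treatment contrasts"
            if criterion.kind == "DA" or 0.0 < (criterion.lambda1 or 0.0) < 1.0
            else f"contrast mu_0 - mu_{1 if criterion.lambda1 == 1.0 else 2}"
        )
        raise InfeasibleDesignError(
            f"no feasible allocation yields a finite criterion: {offending} "
            "cannot be estimated within the budget"
        )

    candidates = [t for t in candidates if t[0] <= best * (1.0 + TIE_RTOL)]
    candidates.sort(key=lambda t: (t[1], t[2]))
    best_val, _, best_counts = candidates[0]
    tie_allocs = [
        Allocation(counts=dict(zip(combos, t[2])), total_cost=t[1])
        for t in candidates
    ]
    optimal = tie_allocs[0]
    return OptimizationResult(
        optimal=optimal,
        criterion=criterion,
        criterion_value=best_val,
        n_evaluated=n_evaluated,
        ties=tie_allocs,
    )


def uniform_allocation(costs: CostSpec, scenario: DesignScenario) -> Allocation:
    """Largest equal integer count per combination that fits the budget."""
    round_cost = sum(combination_cost(costs, c) for c in scenario.combinations)
    n = _max_count(costs.budget, round_cost)
    if n == 0:
        raise InfeasibleDesignError(
            "budget too small for a uniform design: one subject per "
            f"combination costs {round_cost}, budget is {costs.budget}"
        )
    counts = {c: n for c in scenario.combinations}
    return Allocation(counts=counts, total_cost=n * round_cost)


def complete_design_size(costs: CostSpec) -> int:
    """Number of subjects ``floor(B / C_s012)`` in the complete design."""
    unit = combination_cost(costs, COMPLETE)
    if unit <= 0:
        raise InfeasibleDesignError("complete-design cost per subject must be > 0")
    return _max_count(costs.budget, unit)


def complete_allocation(costs: CostSpec) -> Allocation:
    n = complete_design_size(costs)
    return Allocation(
        counts={COMPLETE: n}, total_cost=n * combination_cost(costs, COMPLETE)
    )


def allocation_criterion(
    cov: CovarianceSpec, allocation: Allocation, criterion: CriterionSpec
) -> float:
    """Criterion value of a given allocation (``inf`` if non-estimable)."""
    D = cov.matrix()
    M = model.information_matrix(allocation, D)
    return criterion_value(model.mean_covariance(M), criterion)


def evaluate_grid(
    costs: CostSpec,
    cov: CovarianceSpec,
    scenario: DesignScenario,
    lambda1: float | None = None,
):
    """Tabulate every feasible allocation with its contrast variances.

    Returns a pandas DataFrame with one row per member of Omega:
    count columns (``N01`` etc.), ``cost``, ``phi01``, ``phi02``,
    ``phi_da`` and, when ``lambda1`` is given, ``phi_compound``.
    Intended for modest design spaces (scenario 1); scenario 2 at large
    budgets produces millions of rows.
    """
    import pandas as pd

    combos = scenario.combinations
    unit_costs = np.array([combination_cost(costs, c) for c in combos])
    D = cov.matrix()
    infos = [model.combination_information(D, c) for c in combos]
    pair_var = _pair_variances(cov)

    frames = []
    for batch in _count_batches(unit_costs, costs.budget):
        phi01, phi02, phida = _batch_phis(batch, combos, infos, pair_var)
        data = {f"N{c.label}": batch[:, j] for j, c in enumerate(combos)}
        data["cost"] = batch.astype(float) @ unit_costs
        data["phi01"] = phi01
        data["phi02"] = phi02
        data["phi_da"] = phida
        if lambda1 is not None:
            data["phi_compound"] = _criterion_from_phis(
                CriterionSpec("compound", lambda1), phi01, phi02, phida
            )
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)
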