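"""Benchmark report grids and the consultation-time worked example.

The benchmark grids evaluate the optimizer over a standard panel of
settings — budget 50,000, overhead 100 per subject, three cost triples
(10,20,20) / (10,20,30) / (10,20,40), three variance triples (1,1,1) /
(1,2,3) / (1,2,4), all pairwise correlations 0.5 — under the compound
criterion at lambda1 of 0.25, 0.5 and 0.75 and under D_A.  Four reports
are available: optimal allocations for scenario 1 and scenario 2, the
efficiency of the uniform allocation relative to the optimum, and the
efficiency of the incomplete-design optima relative to the complete
within-subject design.

The worked example plans a primary-care trial comparing consultation
times of 10 (standard), 15 and 20 minutes, where each general
practitioner can evaluate the standard plus one longer time: budget
100,000 euros, overhead 500, per-condition compensations (0, 423.6,
635.4), stress-score variances (100, 125, 150) and correlations 0.3.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

from . import allocate, criteria, power
from .allocate import (
    COMPLETE_DESIGN,
    SCENARIO_1,
    SCENARIO_2,
    Allocation,
    CostSpec,
    DesignScenario,
)
from .model import COMPLETE, CovarianceSpec

__all__ = [
    "BENCHMARK_BUDGET",
    "BENCHMARK_OVERHEAD",
    "BENCHMARK_COSTS",
    "BENCHMARK_VARIANCES",
    "BENCHMARK_RHO",
    "benchmark_criteria",
    "optimal_allocation_table",
    "uniform_efficiency_table",
    "complete_efficiency_table",
    "reference_table",
    "sweep_lambda",
    "consultation_example",
    "EXAMPLE_COSTS",
    "EXAMPLE_COV",
]

BENCHMARK_BUDGET = 50_000.0
BENCHMARK_OVERHEAD = 100.0
BENCHMARK_COSTS = ((10.0, 20.0, 20.0), (10.0, 20.0, 30.0), (10.0, 20.0, 40.0))
BENCHMARK_VARIANCES = ((1.0, 1.0, 1.0), (1.0, 2.0, 3.0), (1.0, 2.0, 4.0))
BENCHMARK_RHO = 0.5

# Consultation-time example: compensations offset the consults lost to
# longer appointments (40 and 60 ten-minute consults at 10.59 euros).
EXAMPLE_COSTS = CostSpec(
    overhead=500.0, per_condition=(0.0, 423.6, 635.4), budget=100_000.0
)
EXAMPLE_COV = CovarianceSpec(
    variances=(100.0, 125.0, 150.0), correlations=(0.3, 0.3, 0.3)
)


def benchmark_criteria() -> list[criteria.CriterionSpec]:
    return [
        criteria.compound(0.25),
        criteria.compound(0.5),
        criteria.compound(0.75),
        criteria.DA(),
    ]


@lru_cache(maxsize=None)
def _benchmark_optimum(
    scenario_name: str,
    criterion_kind: str,
    lambda1: float | None,
    variances: tuple[float, float, float],
    cost_triple: tuple[float, float, float],
):
    """Cached optimizer run for one benchmark cell."""
    scenario = allocate.scenario_by_name(scenario_name)
    criterion = criteria.CriterionSpec(criterion_kind, lambda1)
    cov = CovarianceSpec(variances, (BENCHMARK_RHO,) * 3)
    costs = CostSpec(BENCHMARK_OVERHEAD, cost_triple, BENCHMARK_BUDGET)
    return allocate.optimize_allocation(costs, cov, scenario, criterion)


def _benchmark_rows():
    for criterion in benchmark_criteria():
        for variances in BENCHMARK_VARIANCES:
            for cost_triple in BENCHMARK_COSTS:
                yield criterion, variances, cost_triple


def optimal_allocation_table(scenario: DesignScenario) -> pd.DataFrame:
    """Optimal allocations over the benchmark panel for one scenario."""
    rows = []
    for criterion, variances, cost_triple in _benchmark_rows():
        result = _benchmark_optimum(
            scenario.name, criterion.kind, criterion.lambda1, variances, cost_triple
        )
        row = {
            "criterion": criterion.kind,
            "lambda1": criterion.lambda1,
            "variances": variances,
            "costs": cost_triple,
        }
        row.update(result.optimal.as_dict())
        row["N_total"] = result.optimal.total_n
        row["phi"] = result.criterion_value
        rows.append(row)
    return pd.DataFrame(rows)


def uniform_efficiency_table() -> pd.DataFrame:
    """Efficiency of the uniform allocation relative to the optimum.

    Columns ``RE_scenario1`` and ``RE_scenario2`` give, per benchmark
    cell, the relative efficiency of the uniform allocation under the
    incomplete designs of scenarios 1 and 2.
    """
    rows = []
    for criterion, variances, cost_triple in _benchmark_rows():
        cov = CovarianceSpec(variances, (BENCHMARK_RHO,) * 3)
        costs = CostSpec(BENCHMARK_OVERHEAD, cost_triple, BENCHMARK_BUDGET)
        row = {
            "criterion": criterion.kind,
            "lambda1": criterion.lambda1,
            "variances": variances,
            "costs": cost_triple,
        }
        for scenario, col in ((SCENARIO_1, "RE_scenario1"), (SCENARIO_2, "RE_scenario2")):
            result = _benchmark_optimum(
                scenario.name, criterion.kind, criterion.lambda1, variances, cost_triple
            )
            uniform = allocate.uniform_allocation(costs, scenario)
            phi_uniform = allocate.allocation_criterion(cov, uniform, criterion)
            row[col] = criteria.relative_efficiency(
                criterion, result.criterion_value, phi_uniform
            )
        rows.append(row)
    return pd.DataFrame(rows)


def complete_efficiency_table() -> pd.DataFrame:
    """Efficiency of the incomplete-design optima vs the complete design.

    The complete design enrols ``floor(B / C_s012)`` subjects, so
    ``var(mu_hat) = D / N_012``; the same criterion and efficiency
    formulas are applied to it as to the incomplete designs.
    """
    rows = []
    for criterion, variances, cost_triple in _benchmark_rows():
        cov = CovarianceSpec(variances, (BENCHMARK_RHO,) * 3)
        costs = CostSpec(BENCHMARK_OVERHEAD, cost_triple, BENCHMARK_BUDGET)
        complete = allocate.complete_allocation(costs)
        phi_complete = allocate.allocation_criterion(cov, complete, criterion)
        row = {
            "criterion": criterion.kind,
            "lambda1": criterion.lambda1,
            "variances": variances,
            "costs": cost_triple,
            "N012": complete.total_n,
        }
        for scenario, col in ((SCENARIO_1, "RE_scenario1"), (SCENARIO_2, "RE_scenario2")):
            result = _benchmark_optimum(
                scenario.name, criterion.kind, criterion.lambda1, variances, cost_triple
            )
            row[col] = criteria.relative_efficiency(
                criterion, phi_complete, result.criterion_value
            )
        rows.append(row)
    return pd.DataFrame(rows)


def reference_table(which: int) -> pd.DataFrame:
    """One of the four benchmark reports.

    1: scenario-1 optimal allocations; 2: scenario-2 optimal
    allocations; 3: uniform-allocation efficiencies; 4: efficiencies
    relative to the complete design.
    """
    if which == 1:
        return optimal_allocation_table(SCENARIO_1)
    if which == 2:
        return optimal_allocation_table(SCENARIO_2)
    if which == 3:
        return uniform_efficiency_table()
    if which == 4:
        return complete_efficiency_table()
    raise ValueError(f"report number must be 1-4, got {which}")


def sweep_lambda(
    costs: CostSpec,
    cov: CovarianceSpec,
    scenario: DesignScenario,
    steps: int = 101,
) -> pd.DataFrame:
    """Optimal allocation as a function of the compound weight lambda1.

    Evaluates ``steps`` equally spaced weights over [0, 1].  The optimal
    count for the placebo+treatment-1 pair is a nondecreasing step
    function of lambda1 (and the other pair nonincreasing).
    """
    if steps < 2:
        raise ValueError("need at least 2 sweep steps")
    rows = []
    for lam in np.linspace(0.0, 1.0, steps):
        result = allocate.optimize_allocation(
            costs, cov, scenario, criteria.compound(float(lam))
        )
        row = {"lambda1": float(lam)}
        row.update(result.optimal.as_dict())
        row["N_total"] = result.optimal.total_n
        row["phi"] = result.criterion_value
        rows.append(row)
    return pd.DataFrame(rows)


def consultation_example(
    lambda1: float = 0.75, sweep_steps: int = 101
) -> dict:
    """Full design analysis of the consultation-time trial.

    Returns the lambda1 sweep, the optimum at the requested weight with
    its cost, the uniform-allocation comparison, the contrast variances
    and the detectable-effect / power panel (one-sided alpha 0.05,
    target power 0.8; small and medium standardized effects d = 0.2 and
    d = 0.5).
    """
    costs, cov = EXAMPLE_COSTS, EXAMPLE_COV
    criterion = criteria.compound(lambda1)
    result = allocate.optimize_allocation(costs, cov, SCENARIO_1, criterion)
    optimal = result.optimal

    uniform = allocate.uniform_allocation(costs, SCENARIO_1)
    phi_uniform = allocate.allocation_criterion(cov, uniform, criterion)
    re_uniform = criteria.relative_efficiency(
        criterion, result.criterion_value, phi_uniform
    )

    from . import model

    D = cov.matrix()
    mc = model.mean_covariance(model.information_matrix(optimal, D))
    contrast_vars = {t: model.contrast_variance(mc, t) for t in (1, 2)}

    spec = power.PowerSpec(alpha=0.05, sided=1, power=0.8)
    panel = {}
    for t in (1, 2):
        var_t = cov.variances[t]
        effect = power.detectable_effect_size(contrast_vars[t], spec)
        d = power.standardized_effect(effect, cov.variances[0], var_t)
        powers = {}
        for label, d_target in (("small", 0.2), ("medium", 0.5)):
            raw = power.effect_from_standardized(d_target, cov.variances[0], var_t)
            powers[label] = power.power_for_effect(
                contrast_vars[t],
                power.PowerSpec(alpha=0.05, sided=1, power=None, effect=raw),
            )
        panel[t] = {
            "contrast_variance": contrast_vars[t],
            "detectable_effect": effect,
            "cohens_d": d,
            "power": powers,
        }

    sweep = sweep_lambda(costs, cov, SCENARIO_1, steps=sweep_steps)

    return {
        "lambda1": lambda1,
        "optimal": optimal,
        "criterion_value": result.criterion_value,
        "total_n": optimal.total_n,
        "total_cost": optimal.total_cost,
        "uniform": uniform,
        "re_uniform": re_uniform,
        "contrasts": panel,
        "sweep": sweep,
    }
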