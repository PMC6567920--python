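"""Bottom-up micro-costing of diagnostic algorithms.

Each test's annual cost splits into a fixed component (straight-line
annualized capital plus maintenance) and a variable per-test component
(consumables, operator time, and physician time for sample collection).
Algorithm-level totals scale variable costs by the expected yearly test
volumes produced by the decision model.

The brushing rule: physician sampling time is billed once per sampled
patient.  In the parallel arm the arbiter test re-uses the brushing already
taken for the parallel partner, so its sampling contribution is suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Dict, Mapping, Optional

import numpy as np

from .distributions import DistributionSpec

__all__ = [
    "TestCostParams",
    "CostValues",
    "CostBreakdown",
    "AlgorithmCost",
    "annual_cost_components",
    "algorithm_annual_cost",
]

#: cost-parameter field names, in reporting order
COST_FIELDS = (
    "capital_cost",
    "equipment_lifespan",
    "annual_maintenance",
    "consumables",
    "operator_rate",
    "test_duration",
    "physician_rate",
    "sampling_time",
)


@dataclass(frozen=True)
class TestCostParams:
    """Uncertainty specs for one test's cost inputs (all € or hours/years)."""

    capital_cost: DistributionSpec
    equipment_lifespan: DistributionSpec
    annual_maintenance: DistributionSpec
    consumables: DistributionSpec
    operator_rate: DistributionSpec
    test_duration: DistributionSpec
    physician_rate: DistributionSpec
    sampling_time: DistributionSpec

    def items(self):
        for f in fields(self):
            yield f.name, getattr(self, f.name)

    def validate(self) -> None:
        for name, spec in self.items():
            spec.validate()
            if spec.best < 0:
                raise ValueError(f"cost parameter {name} must be non-negative")
        if self.equipment_lifespan.best <= 0:
            raise ValueError("equipment lifespan must be positive")


@dataclass(frozen=True)
class CostValues:
    """Point (or vector) realizations of one test's cost inputs."""

    capital_cost: float
    equipment_lifespan: float
    annual_maintenance: float
    consumables: float
    operator_rate: float
    test_duration: float
    physician_rate: float
    sampling_time: float

    @classmethod
    def from_mapping(cls, values: Mapping[str, float], prefix: str) -> "CostValues":
        return cls(**{f: values[f"{prefix}.{f}"] for f in COST_FIELDS})


@dataclass(frozen=True)
class CostBreakdown:
    """Annual cost of one test type within an algorithm."""

    test: str
    fixed_annual: float
    variable_per_test: float
    tests_performed: float
    total_annual: float


@dataclass(frozen=True)
class AlgorithmCost:
    """Per-test breakdowns plus algorithm total (€/yr)."""

    algorithm: str
    breakdowns: Dict[str, CostBreakdown]
    overhead_annual: float
    total_annual: float


def annual_cost_components(cv: CostValues, include_sampling: bool = True):
    """Split one test's cost into (fixed €/yr, variable €/test).

    ``fixed = capital/lifespan + maintenance``;
    ``variable = consumables + operator_rate*duration
    [+ physician_rate*sampling_time]``.

    ``include_sampling=False`` drops the physician sampling term (shared
    brushing).  Raises ``ZeroDivisionError``-style ``ValueError`` on a zero
    lifespan.
    """
    if np.any(np.asarray(cv.equipment_lifespan) <= 0):
        raise ValueError("equipment lifespan must be positive")
    fixed = cv.capital_cost / cv.equipment_lifespan + cv.annual_maintenance
    variable = cv.consumables + cv.operator_rate * cv.test_duration
    if include_sampling:
        variable = variable + cv.physician_rate * cv.sampling_time
    return fixed, variable


def algorithm_annual_cost(
    algorithm,
    cost_values: Mapping[str, CostValues],
    volumes: Mapping[str, float],
    overhead_per_patient: float = 0.0,
    n_patients: float = 0.0,
) -> AlgorithmCost:
    """Total annual cost of an algorithm given per-test volumes.

    Fixed costs accrue for every test type the algorithm can use; variable
    costs scale with volume.  The optional per-patient overhead term (default
    0) is billed on the referral cohort and lets users calibrate toward
    published aggregate figures without touching unit costs.
    """
    tests = algorithm.tests()
    shared = algorithm.shared_brushing_tests()
    breakdowns: Dict[str, CostBreakdown] = {}
    total = 0.0
    for t in tests:
        if t not in cost_values:
            raise KeyError(f"no cost parameters for test {t!r} "
                           f"required by algorithm {algorithm.name!r}")
        fixed, variable = annual_cost_components(
            cost_values[t], include_sampling=t not in shared)
        vol = volumes.get(t, 0.0)
        subtotal = fixed + variable * vol
        breakdowns[t] = CostBreakdown(t, fixed, variable, vol, subtotal)
        total = total + subtotal
    overhead = overhead_per_patient * n_patients if tests else 0.0
    return AlgorithmCost(algorithm.name, breakdowns, overhead, total + overhead)
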