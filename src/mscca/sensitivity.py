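"""One-way (tornado) sensitivity analysis.

Each factor is perturbed to 90% and 110% of its base value while every
other input stays at base; the model is rerun for both scenarios of the
pair and the chosen metric recomputed.  Results are sorted by the range
``|high - low|`` (tornado order).  The default metric is the incremental
discounted total cost, comparator minus reference.

The nine standard factors mirror the usual drivers of such analyses:
the three price points of the high-efficacy therapy (year 1, year 2,
year 2 onwards), its disability-progression hazard ratio, cohort size,
start age, sex mix, the discount rates (costs and effects jointly), and
the annual relapse unit cost.  Cohort size only rescales population
totals, so it is a documented no-op on per-patient metrics.  Perturbed
proportions are clamped to [0, 1] and the clamping recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .costs import compute_cost_report
from .engine import run_scenario
from .parameters import ParameterSet
from .scenarios import ScenarioSpec

__all__ = [
    "SensitivityResult",
    "DEFAULT_FACTORS",
    "incremental_total_cost",
    "univariate_sensitivity",
]


@dataclass
class SensitivityResult:
    factor: str
    low_value: float
    high_value: float
    base_value: float
    notes: tuple[str, ...] = ()

    @property
    def range(self) -> float:
        return abs(self.high_value - self.low_value)


def _scale_omb_price_year1(ps: ParameterSet, s: float) -> list[str]:
    ps.treatments["OMB"].annual_drug_cost_year1 *= s
    return []


def _scale_omb_price_year2(ps: ParameterSet, s: float) -> list[str]:
    t = ps.treatments["OMB"]
    if t.annual_drug_cost_year2 is None:
        t.annual_drug_cost_year2 = t.annual_drug_cost_subsequent
    t.annual_drug_cost_year2 *= s
    return []


def _scale_omb_price_from_year2(ps: ParameterSet, s: float) -> list[str]:
    # the explicit year-2 price (if any) inherits the perturbation too:
    # "from year 2 onwards" covers every year after the first
    t = ps.treatments["OMB"]
    t.annual_drug_cost_subsequent *= s
    if t.annual_drug_cost_year2 is not None:
        t.annual_drug_cost_year2 *= s
    return []


def _scale_omb_hr(ps: ParameterSet, s: float) -> list[str]:
    ps.treatments["OMB"].hr_progression *= s
    return []


def _scale_cohort_size(ps: ParameterSet, s: float) -> list[str]:
    ps.baseline.cohort_size *= s
    return []


def _scale_start_age(ps: ParameterSet, s: float) -> list[str]:
    ps.baseline.start_age *= s
    return []


def _scale_male_fraction(ps: ParameterSet, s: float) -> list[str]:
    v = ps.baseline.male_fraction * s
    notes = []
    if v > 1.0:
        notes.append(f"male_fraction clamped from {v:.4f} to 1.0")
        v = 1.0
    ps.baseline.male_fraction = v
    return notes


def _scale_discount_rates(ps: ParameterSet, s: float) -> list[str]:
    ps.economics.discount_rate_costs *= s
    ps.economics.discount_rate_effects *= s
    return []


def _scale_relapse_cost(ps: ParameterSet, s: float) -> list[str]:
    ps.economics.annual_relapse_cost *= s
    return []


#: factor name -> in-place perturbation on a copied ParameterSet
DEFAULT_FACTORS: dict[str, Callable[[ParameterSet, float], list[str]]] = {
    "omb_drug_cost_year1": _scale_omb_price_year1,
    "omb_drug_cost_year2": _scale_omb_price_year2,
    "omb_drug_cost_from_year2": _scale_omb_price_from_year2,
    "omb_hr_6cdp": _scale_omb_hr,
    "cohort_size": _scale_cohort_size,
    "start_age": _scale_start_age,
    "male_fraction": _scale_male_fraction,
    "discount_rates": _scale_discount_rates,
    "annual_relapse_cost": _scale_relapse_cost,
}


def incremental_total_cost(
    params: ParameterSet, scenario_pair: tuple[ScenarioSpec, ScenarioSpec]
) -> float:
    """Discounted total cost of the comparator minus the reference scenario."""
    reference, comparator = scenario_pair
    totals = []
    for spec in (reference, comparator):
        trace = run_scenario(params, spec)
        totals.append(compute_cost_report(trace, params, spec).total)
    return totals[1] - totals[0]


def univariate_sensitivity(
    params: ParameterSet,
    scenario_pair: tuple[ScenarioSpec, ScenarioSpec],
    metric: Callable[[ParameterSet, tuple[ScenarioSpec, ScenarioSpec]], float]
    | None = None,
    factors: dict[str, Callable[[ParameterSet, float], list[str]]] | None = None,
    perturbation: float = 0.10,
) -> list[SensitivityResult]:
    """Rerun the model with each factor at -10% / +10% of base.

    Returns one :class:`SensitivityResult` per factor, sorted by
    descending range.  Deterministic: the base ParameterSet is never
    mutated, each rerun starts from an independent copy.
    """
    metric = metric or incremental_total_cost
    factors = DEFAULT_FACTORS if factors is None else factors
    base_value = metric(params, scenario_pair)

    results = []
    for name, perturb in factors.items():
        values = {}
        notes: list[str] = []
        for label, scale in (("low", 1.0 - perturbation), ("high", 1.0 + perturbation)):
            perturbed = params.copy()
            notes += [f"{label}: {n}" for n in perturb(perturbed, scale)]
            perturbed.require_valid()
            values[label] = metric(perturbed, scenario_pair)
        results.append(
            SensitivityResult(
                factor=name,
                low_value=values["low"],
                high_value=values["high"],
                base_value=base_value,
                notes=tuple(notes),
            )
        )
    results.sort(key=lambda r: r.range, reverse=True)
    return results
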