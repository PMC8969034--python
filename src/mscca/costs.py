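"""Discounted societal costs per patient, by category.

Costs attach to state membership at the start of each cycle (cycles
0..horizon-1, discounted by ``(1+r)^-t``; no half-cycle correction).
Drug prices are keyed to time since the active therapy's initiation
*within the scenario*, so a mid-horizon switch prices the new therapy's
loading year correctly.  Indirect productivity-loss costs accrue only
while the cohort is below retirement age.

Relapse costs are estimated separately from the per-state cost inputs
and added on top of the direct + indirect sum; because the per-state
inputs may already cover part of the relapse burden, the grand total is
an upper bound (see the ``overestimation`` note in the report).
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import CohortTrace, ON_DMT
from .parameters import (
    DIRECT_COST_CATEGORIES,
    INDIRECT_COST_CATEGORIES,
    ParameterSet,
    StateValuation,
    TreatmentEffect,
)
from .scenarios import ScenarioSpec, active_treatment, treatment_start_cycle

__all__ = [
    "discount_factor",
    "dmt_costs",
    "state_cost_accumulation",
    "relapse_costs",
    "CostReport",
    "build_cost_report",
    "compute_cost_report",
]


def discount_factor(year: int, rate: float) -> float:
    """Present-value factor ``(1 + rate)^-year`` (year 0 is undiscounted)."""
    if year < 0:
        raise ValueError(f"year must be non-negative, got {year}")
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    return (1.0 + rate) ** (-year)


def dmt_costs(
    trace: CohortTrace,
    treatments: dict[str, TreatmentEffect],
    spec: ScenarioSpec,
    rate: float,
) -> float:
    """Discounted drug-acquisition costs per patient.

    Each cycle, on-DMT living mass pays the active therapy's annual
    price — the year-1 price in that therapy's first year of use within
    the scenario, the subsequent-year price after.  Off-DMT mass pays
    nothing.
    """
    total = 0.0
    for t in range(trace.horizon):
        name = active_treatment(spec, t)
        effect = treatments[name]
        years_on = t - treatment_start_cycle(spec, t)
        price = effect.drug_cost(years_on)
        if price == 0.0:
            continue
        on_mass = float(trace.states[t].occupancy[:, ON_DMT, :].sum())
        total += on_mass * price * discount_factor(t, rate)
    return total


def state_cost_accumulation(
    trace: CohortTrace,
    valuation: StateValuation,
    rate: float,
    retirement_age: float = float("inf"),
) -> dict[str, float]:
    """Discounted per-category costs driven by per-EDSS annual inputs.

    Covers every non-DMT direct category and both indirect
    (productivity-loss) categories; the indirect ones accrue only in
    cycles where the cohort is below ``retirement_age``.
    """
    totals = {cat: 0.0 for cat in (*DIRECT_COST_CATEGORIES, *INDIRECT_COST_CATEGORIES)}
    indirect = valuation.indirect_costs()
    for t in range(trace.horizon):
        state = trace.states[t]
        dist = state.edss_distribution()
        df = discount_factor(t, rate)
        for cat in DIRECT_COST_CATEGORIES:
            totals[cat] += float(dist @ valuation.direct_costs[cat]) * df
        if state.current_age < retirement_age:
            for cat in INDIRECT_COST_CATEGORIES:
                totals[cat] += float(dist @ indirect[cat]) * df
    return totals


def relapse_costs(trace: CohortTrace, annual_relapse_cost: float, rate: float) -> float:
    """Discounted relapse-related costs (expected relapses x unit cost)."""
    return float(
        sum(
            trace.expected_relapses_per_cycle[t]
            * annual_relapse_cost
            * discount_factor(t, rate)
            for t in range(trace.horizon)
        )
    )


@dataclass
class CostReport:
    """Discounted per-patient cost breakdown with percentage shares.

    ``direct`` includes the DMT category; ``shares`` expresses each
    direct/indirect category as a percentage of its subtotal, the two
    subtotals as percentages of the direct + indirect sum, and relapse
    costs as a percentage of the direct + indirect sum (the lower cost
    limit).  Shares are kept at full precision; rounding is a
    presentation concern.
    """

    scenario_label: str
    direct: dict[str, float]
    indirect: dict[str, float]
    direct_subtotal: float
    indirect_subtotal: float
    direct_plus_indirect: float
    relapse_costs: float
    total: float
    shares: dict[str, float]
    note: str = (
        "Relapse costs are estimated separately and added to the direct + "
        "indirect sum; since the per-state cost inputs may already include "
        "part of the relapse burden, the total is an overestimation."
    )

    def metrics(self) -> dict[str, float]:
        out = {f"direct_{k}": v for k, v in self.direct.items()}
        out.update({f"indirect_{k}": v for k, v in self.indirect.items()})
        out.update(
            {
                "sum_direct": self.direct_subtotal,
                "sum_indirect": self.indirect_subtotal,
                "sum_direct_indirect": self.direct_plus_indirect,
                "relapse_costs": self.relapse_costs,
                "total": self.total,
            }
        )
        return out


def build_cost_report(
    dmt: float,
    state_costs: dict[str, float],
    relapse: float,
    scenario_label: str = "",
) -> CostReport:
    """Assemble subtotals, the grand total and percentage shares.

    ``state_costs`` must contain every non-DMT direct category and both
    indirect categories (as produced by :func:`state_cost_accumulation`).
    """
    missing = {
        *DIRECT_COST_CATEGORIES,
        *INDIRECT_COST_CATEGORIES,
    } - set(state_costs)
    if missing:
        raise ValueError(f"state_costs missing categories: {sorted(missing)}")
    if dmt < 0 or relapse < 0 or any(v < 0 for v in state_costs.values()):
        raise ValueError("cost components must be non-negative")

    direct = {"dmt": dmt}
    direct.update({cat: state_costs[cat] for cat in DIRECT_COST_CATEGORIES})
    indirect = {cat: state_costs[cat] for cat in INDIRECT_COST_CATEGORIES}
    direct_subtotal = sum(direct.values())
    indirect_subtotal = sum(indirect.values())
    combined = direct_subtotal + indirect_subtotal

    def pct(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else 0.0

    shares = {f"direct_{k}_of_direct": pct(v, direct_subtotal) for k, v in direct.items()}
    shares.update(
        {f"indirect_{k}_of_indirect": pct(v, indirect_subtotal) for k, v in indirect.items()}
    )
    shares["direct_of_combined"] = pct(direct_subtotal, combined)
    shares["indirect_of_combined"] = pct(indirect_subtotal, combined)
    shares["relapse_of_combined"] = pct(relapse, combined)

    return CostReport(
        scenario_label=scenario_label,
        direct=direct,
        indirect=indirect,
        direct_subtotal=direct_subtotal,
        indirect_subtotal=indirect_subtotal,
        direct_plus_indirect=combined,
        relapse_costs=relapse,
        total=combined + relapse,
        shares=shares,
    )


def compute_cost_report(
    trace: CohortTrace, params: ParameterSet, spec: ScenarioSpec
) -> CostReport:
    """All cost components for one scenario trace, assembled into a report."""
    econ = params.economics
    rate = econ.discount_rate_costs
    dmt = dmt_costs(trace, params.treatments, spec, rate)
    state_costs = state_cost_accumulation(
        trace, params.valuation, rate, econ.retirement_age
    )
    relapse = relapse_costs(trace, econ.annual_relapse_cost, rate)
    return build_cost_report(dmt, state_costs, relapse, scenario_label=spec.label)
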