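import numpy as np
import pytest

from mscca import (
    CohortState,
    CohortTrace,
    ScenarioSpec,
    build_cost_report,
    compute_cost_report,
    discount_factor,
    dmt_costs,
    relapse_costs,
    run_scenario,
    state_cost_accumulation,
)
from mscca.engine import MALE, ON_DMT
from mscca.parameters import (
    DIRECT_COST_CATEGORIES,
    INDIRECT_COST_CATEGORIES,
    N_EDSS,
    TreatmentEffect,
)


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "year, rate, expected",
        [(0, 0.03, 1.0), (1, 0.03, 1 / 1.03), (5, 0.0, 1.0), (2, 0.1, 1.1**-2)],
    )
    def test_closed_form(self, year, rate, expected):
        assert discount_factor(year, rate) == pytest.approx(expected, abs=1e-12)

    def test_negative_year_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03)


def _flat_trace(horizon=10, relapses=0.0):
    """Everyone alive at EDSS 0, on DMT, for `horizon` years."""
    occ = np.zeros((N_EDSS, 2, 2))
    occ[0, ON_DMT, MALE] = 1.0
    states = [CohortState(occ.copy(), 0.0, 40.0 + t, t) for t in range(horizon + 1)]
    return CohortTrace(
        states,
        np.zeros((horizon, 2)),
        np.full(horizon, relapses),
        ["OMB"] * horizon,
    )


class TestDmtCosts:
    def test_zero_prices(self, zero_mortality_worked):
        ps = zero_mortality_worked.copy()
        for t in ps.treatments.values():
            t.annual_drug_cost_year1 = t.annual_drug_cost_subsequent = 0.0
        spec = ScenarioSpec("o", (("OMB", 10),), 10)
        trace = run_scenario(ps, spec)
        assert dmt_costs(trace, ps.treatments, spec, 0.03) == 0.0

    def test_flat_price_undiscounted(self):
        trace = _flat_trace()
        treatments = {"OMB": TreatmentEffect("OMB", 1, 1, 10000.0, 10000.0)}
        spec = ScenarioSpec("o", (("OMB", 10),), 10)
        assert dmt_costs(trace, treatments, spec, 0.0) == pytest.approx(100000.0)

    def test_switch_pricing_brute_force(self, zero_mortality_worked):
        """Year-1 price applies in the first year of each therapy's use."""
        ps = zero_mortality_worked
        spec = ScenarioSpec("b", (("DMF", 5), ("OMB", 5)), 10)
        trace = run_scenario(ps, spec)
        rate = 0.03
        expected = 0.0
        for t in range(10):
            on_mass = trace.states[t].occupancy[:, ON_DMT, :].sum()
            if t < 5:
                price = 8000.0  # DMF flat
            elif t == 5:
                price = 12000.0  # OMB loading year
            else:
                price = 10000.0
            expected += on_mass * price * (1.03) ** (-t)
        assert dmt_costs(trace, ps.treatments, spec, rate) == pytest.approx(
            expected, abs=1e-9
        )

    def test_explicit_year2_price_used(self):
        trace = _flat_trace(horizon=3)
        treatments = {
            "OMB": TreatmentEffect("OMB", 1, 1, 100.0, 1.0, annual_drug_cost_year2=10.0)
        }
        spec = ScenarioSpec("o", (("OMB", 3),), 3)
        assert dmt_costs(trace, treatments, spec, 0.0) == pytest.approx(100 + 10 + 1)


class TestStateCosts:
    def test_all_zero_costs(self, zero_mortality_worked):
        ps = zero_mortality_worked.copy()
        for cat in DIRECT_COST_CATEGORIES:
            ps.valuation.direct_costs[cat] = np.zeros(N_EDSS)
        ps.valuation.short_term_absence_cost = np.zeros(N_EDSS)
        ps.valuation.long_term_absence_cost = np.zeros(N_EDSS)
        trace = run_scenario(ps, ScenarioSpec("o", (("OMB", 10),), 10))
        totals = state_cost_accumulation(trace, ps.valuation, 0.03, 67.0)
        assert all(v == 0.0 for v in totals.values())

    def test_single_state_two_years(self, worked):
        trace = _flat_trace(horizon=2)
        totals = state_cost_accumulation(trace, worked.valuation, 0.0, 67.0)
        # worked fixture: inpatient at EDSS 0 costs 1000/year
        assert totals["inpatient_care"] == pytest.approx(2000.0)

    def test_indirect_costs_stop_at_retirement(self, worked):
        trace = _flat_trace(horizon=2)
        # ages 40, 41 -> both cycles count
        full = state_cost_accumulation(trace, worked.valuation, 0.0, 67.0)
        # retirement at 41 -> only the first cycle counts for indirect
        capped = state_cost_accumulation(trace, worked.valuation, 0.0, 41.0)
        assert capped["short_term_absence"] == pytest.approx(
            full["short_term_absence"] / 2
        )
        assert capped["inpatient_care"] == full["inpatient_care"]


class TestRelapseCosts:
    def test_zero_relapses(self):
        assert relapse_costs(_flat_trace(relapses=0.0), 2662.0, 0.03) == 0.0

    def test_single_relapse_in_year_zero(self):
        trace = _flat_trace(horizon=1, relapses=1.0)
        assert relapse_costs(trace, 2662.0, 0.03) == pytest.approx(2662.0)

    def test_linear_in_arr(self, zero_mortality_worked):
        ps = zero_mortality_worked.copy()
        spec = ScenarioSpec("o", (("OMB", 10),), 10)
        base = relapse_costs(run_scenario(ps, spec), 2662.0, 0.03)
        ps.natural_history.arr_by_edss = ps.natural_history.arr_by_edss * 2
        doubled = relapse_costs(run_scenario(ps, spec), 2662.0, 0.03)
        assert doubled == pytest.approx(2 * base, rel=1e-12)


class TestCostReport:
    @pytest.mark.parametrize("seed", range(20))
    def test_identities_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        state_costs = {
            cat: float(rng.uniform(0, 1e4))
            for cat in (*DIRECT_COST_CATEGORIES, *INDIRECT_COST_CATEGORIES)
        }
        rep = build_cost_report(float(rng.uniform(0, 1e5)), state_costs, float(rng.uniform(0, 1e4)))
        assert rep.direct_subtotal == pytest.approx(sum(rep.direct.values()), abs=1e-6)
        assert rep.indirect_subtotal == pytest.approx(sum(rep.indirect.values()), abs=1e-6)
        assert rep.total == pytest.approx(rep.direct_plus_indirect + rep.relapse_costs)
        assert sum(
            rep.shares[f"direct_{k}_of_direct"] for k in rep.direct
        ) == pytest.approx(100.0)
        assert rep.shares["direct_of_combined"] + rep.shares[
            "indirect_of_combined"
        ] == pytest.approx(100.0)

    def test_missing_category_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_cost_report(0.0, {"inpatient_care": 1.0}, 0.0)

    def test_higher_discount_rate_lowers_every_aggregate(self, default_params, dmf_scenarios):
        ps_lo = default_params.copy()
        ps_hi = default_params.copy()
        ps_hi.economics.discount_rate_costs = 0.06
        spec = dmf_scenarios[0]
        trace = run_scenario(default_params, spec)
        lo = compute_cost_report(trace, ps_lo, spec)
        hi = compute_cost_report(trace, ps_hi, spec)
        for k, v in lo.metrics().items():
            if v > 0:
                assert hi.metrics()[k] < v

    def test_cost_shifting_with_later_switch(self, default_params, dmf_scenarios, dmf_traces):
        """Later switch: DMT costs fall, every care and productivity
        category rises (the superior drug is the costlier one)."""
        reports = [
            compute_cost_report(dmf_traces[s.label], default_params, s)
            for s in dmf_scenarios
        ]
        for earlier, later in zip(reports, reports[1:]):
            assert later.direct["dmt"] < earlier.direct["dmt"]
            for cat in DIRECT_COST_CATEGORIES:
                assert later.direct[cat] > earlier.direct[cat]
            assert later.indirect["long_term_absence"] > earlier.indirect["long_term_absence"]
            assert later.relapse_costs > earlier.relapse_costs
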