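import numpy as np
import pytest

from mscca import (
    CohortState,
    ScenarioSpec,
    SyntheticConfig,
    apply_discontinuation,
    build_cycle_matrix,
    expected_relapses,
    generate_parameter_set,
    run_scenario,
)
from mscca.engine import MALE, FEMALE, OFF_DMT, ON_DMT
from mscca.parameters import (
    N_EDSS,
    MortalityModel,
    NaturalHistory,
    TreatmentEffect,
)


def _flat_mortality(q_male, q_female, hr=1.0):
    ages = np.arange(121)
    q = np.zeros((121, 2))
    q[:, 0], q[:, 1] = q_male, q_female
    ex = np.zeros((121, 2))
    return MortalityModel(ages=ages, death_prob=q, life_expectancy=ex, ms_hazard_ratio=hr)


def _state(occupancy, dead=0.0, age=40.0, cycle=0):
    return CohortState(
        occupancy=np.asarray(occupancy, float), dead_mass=dead,
        current_age=age, cycle_index=cycle,
    )


class TestBuildCycleMatrix:
    def test_identity_composition(self, worked):
        """hr=1 and zero mortality give natural history + absorbing death."""
        nh = worked.natural_history
        M = build_cycle_matrix(
            nh, TreatmentEffect("none"), _flat_mortality(0.0, 0.0), 40, MALE
        )
        np.testing.assert_allclose(M[:N_EDSS, :N_EDSS], nh.transition_matrix, atol=1e-15)
        assert np.all(M[:N_EDSS, N_EDSS] == 0)
        assert M[N_EDSS, N_EDSS] == 1.0

    def test_hand_computed_worsening_entry(self):
        """Two-state fixture: p_worsen=0.2, hr=0.5, p_death=0.1."""
        P = np.eye(N_EDSS)
        P[0, 0], P[0, 1] = 0.8, 0.2
        nh = NaturalHistory(transition_matrix=P, arr_by_edss=np.zeros(N_EDSS))
        M = build_cycle_matrix(
            nh, TreatmentEffect("x", hr_progression=0.5),
            _flat_mortality(0.1, 0.1), 40, MALE,
        )
        adj = 1 - 0.8**0.5  # ~0.105573
        assert M[0, 1] == pytest.approx(0.9 * adj, abs=1e-12)  # ~0.095016
        assert M[0, N_EDSS] == pytest.approx(0.1)
        assert M[0, 0] == pytest.approx(0.9 * (1 - adj), abs=1e-12)

    @pytest.mark.parametrize("seed", range(40))
    def test_rows_sum_to_one_random_fixtures(self, seed):
        """Banded random matrices (stay-dominant, like published
        natural-history data) stay stochastic under any moderate HR."""
        rng = np.random.default_rng(seed)
        P = np.zeros((N_EDSS, N_EDSS))
        for i in range(N_EDSS):
            off = rng.uniform(0, 0.3 / N_EDSS, N_EDSS)
            off[i] = 0.0
            P[i] = off
            P[i, i] = 1.0 - off.sum()
        nh = NaturalHistory(transition_matrix=P, arr_by_edss=np.zeros(N_EDSS))
        eff = TreatmentEffect("x", hr_progression=float(rng.uniform(0.1, 2.0)))
        M = build_cycle_matrix(nh, eff, _flat_mortality(*rng.uniform(0, 0.5, 2)), 50, FEMALE)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(M >= 0)

    def test_overinflating_hazard_ratio_rejected(self):
        """hr > 1 on a row whose worsening mass exhausts the stay
        probability is a degenerate input, not silently clipped."""
        P = np.eye(N_EDSS)
        P[1, 0], P[1, 1], P[1, 2] = 0.5, 0.1, 0.4
        nh = NaturalHistory(transition_matrix=P, arr_by_edss=np.zeros(N_EDSS))
        with pytest.raises(ValueError, match="stay probability"):
            build_cycle_matrix(
                nh, TreatmentEffect("x", hr_progression=5.0),
                _flat_mortality(0.0, 0.0), 40, MALE,
            )

    def test_age_outside_life_table(self, worked):
        with pytest.raises(ValueError, match="life table"):
            build_cycle_matrix(
                worked.natural_history, TreatmentEffect("none"),
                worked.mortality, 500, MALE,
            )


class TestDiscontinuation:
    def test_below_threshold_unchanged(self):
        occ = np.zeros((N_EDSS, 2, 2))
        occ[3, ON_DMT, MALE] = 1.0
        out = apply_discontinuation(_state(occ), threshold=6)
        np.testing.assert_array_equal(out.occupancy, occ)

    def test_mass_above_threshold_moves_off_dmt(self):
        occ = np.zeros((N_EDSS, 2, 2))
        occ[7, ON_DMT, FEMALE] = 0.1
        occ[2, ON_DMT, FEMALE] = 0.9
        out = apply_discontinuation(_state(occ), threshold=6)
        assert out.occupancy[7, ON_DMT, FEMALE] == 0.0
        assert out.occupancy[7, OFF_DMT, FEMALE] == 0.1
        assert out.occupancy.sum() == pytest.approx(1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        occ = rng.random((N_EDSS, 2, 2))
        once = apply_discontinuation(_state(occ), 6)
        twice = apply_discontinuation(once, 6)
        np.testing.assert_array_equal(once.occupancy, twice.occupancy)


class TestExpectedRelapses:
    def test_zero_arr(self):
        occ = np.zeros((N_EDSS, 2, 2))
        occ[1, ON_DMT, MALE] = 1.0
        assert expected_relapses(_state(occ), np.zeros(N_EDSS), TreatmentEffect("x")) == 0

    def test_single_stratum_product(self):
        occ = np.zeros((N_EDSS, 2, 2))
        occ[2, ON_DMT, FEMALE] = 1.0
        arr = np.zeros(N_EDSS)
        arr[2] = 0.7
        eff = TreatmentEffect("x", rr_relapse=0.5)
        assert expected_relapses(_state(occ), arr, eff) == pytest.approx(0.35)

    def test_off_dmt_mass_untreated(self):
        occ = np.zeros((N_EDSS, 2, 2))
        occ[2, ON_DMT, MALE] = 0.5
        occ[2, OFF_DMT, MALE] = 0.5
        arr = np.full(N_EDSS, 0.6)
        eff = TreatmentEffect("x", rr_relapse=0.5)
        assert expected_relapses(_state(occ), arr, eff) == pytest.approx(
            0.5 * 0.6 * 0.5 + 0.5 * 0.6
        )

    def test_brute_force_sum_on_worked_fixture(self, worked):
        trace = run_scenario(worked, ScenarioSpec("omb", (("OMB", 10),), 10))
        state = trace.states[0]
        arr = worked.natural_history.arr_by_edss
        rr = worked.treatments["OMB"].rr_relapse
        brute = 0.0
        for e in range(N_EDSS):
            for sex in (MALE, FEMALE):
                brute += state.occupancy[e, ON_DMT, sex] * arr[e] * rr
                brute += state.occupancy[e, OFF_DMT, sex] * arr[e]
        assert trace.expected_relapses_per_cycle[0] == pytest.approx(brute, abs=1e-14)


class TestRunScenario:
    def test_zero_horizon_returns_baseline_only(self, worked):
        trace = run_scenario(worked, ScenarioSpec("empty", (), 0))
        assert trace.horizon == 0
        assert trace.states[0].dead_mass == 0.0
        np.testing.assert_allclose(
            trace.states[0].edss_distribution(),
            worked.baseline.full_distribution(),
        )

    def test_unknown_treatment_rejected(self, worked):
        with pytest.raises(KeyError, match="XYZ"):
            run_scenario(worked, ScenarioSpec("bad", (("XYZ", 10),), 10))

    def test_indistinguishable_treatments_give_identical_traces(self, worked):
        ps = worked.copy()
        for t in ps.treatments.values():
            t.hr_progression = t.rr_relapse = 1.0
        from mscca import builtin_scenarios

        traces = [run_scenario(ps, s) for s in builtin_scenarios("DMF")]
        ref = traces[0]
        for tr in traces[1:]:
            for a, b in zip(ref.states, tr.states):
                np.testing.assert_array_equal(a.occupancy, b.occupancy)
            np.testing.assert_array_equal(
                ref.expected_relapses_per_cycle, tr.expected_relapses_per_cycle
            )

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_conservation_and_monotone_death(self, seed, dmf_scenarios):
        ps = generate_parameter_set(SyntheticConfig(seed=seed))
        for spec in dmf_scenarios:
            trace = run_scenario(ps, spec)
            dead = [s.dead_mass for s in trace.states]
            for s in trace.states:
                assert s.living_mass() + s.dead_mass == pytest.approx(1.0, abs=1e-10)
            assert np.all(np.diff(dead) >= 0)

    def test_zero_mortality_keeps_everyone_alive(self, zero_mortality_worked):
        trace = run_scenario(
            zero_mortality_worked, ScenarioSpec("omb", (("OMB", 10),), 10)
        )
        assert trace.states[-1].dead_mass == 0.0
        assert trace.new_deaths_per_cycle.sum() == 0.0

    def test_dominance_lower_hr_first_order_dominates(self, default_params):
        """Lower progression HR keeps cumulative mass below any EDSS cutoff."""
        ps = default_params.copy()
        ps.treatments["A"] = TreatmentEffect("A", hr_progression=0.5)
        ps.treatments["B"] = TreatmentEffect("B", hr_progression=0.9)
        ta = run_scenario(ps, ScenarioSpec("a", (("A", 10),), 10))
        tb = run_scenario(ps, ScenarioSpec("b", (("B", 10),), 10))
        for sa, sb in zip(ta.states, tb.states):
            da, db = sa.edss_distribution(), sb.edss_distribution()
            for cutoff in range(N_EDSS):
                assert da[cutoff:].sum() <= db[cutoff:].sum() + 1e-12

    def test_switch_time_monotonicity_of_mean_edss(self, dmf_traces):
        from mscca import mean_edss

        labels = list(dmf_traces)
        finals = [mean_edss(dmf_traces[l]) for l in labels]
        assert finals == sorted(finals)

    def test_death_trajectory_scenario_independent(self, dmf_traces):
        """Uniform mortality HR makes deaths identical across scenarios."""
        ref = next(iter(dmf_traces.values()))
        for tr in dmf_traces.values():
            np.testing.assert_allclose(
                tr.new_deaths_by_sex, ref.new_deaths_by_sex, atol=1e-12
            )

    def test_discontinued_mass_stays_off_dmt(self, default_params):
        trace = run_scenario(default_params, ScenarioSpec("o", (("OMB", 10),), 10))
        threshold = default_params.economics.discontinuation_edss_threshold
        for s in trace.states:
            assert s.occupancy[threshold + 1 :, ON_DMT, :].sum() == 0.0
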