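"""Markov cohort engine.

The cohort is a probability mass over (EDSS 0-9) x (on-DMT / off-DMT) x
(male / female), plus an absorbing dead state.  One cycle is one year —
fixed, not configurable, so that annualized relapse rates, annual cost
inputs and annual discounting share one time unit.

Per cycle, in order:

1. the active treatment is looked up from the scenario;
2. expected relapses are recorded from the start-of-cycle occupancy
   (state membership is valued at the start of each cycle; no
   half-cycle correction anywhere in the model);
3. a transition matrix is built per sex stratum at the current integer
   age — death first (background probability times the MS hazard ratio,
   identical for every living state), then the EDSS move conditional on
   survival, with the treatment hazard ratio applied to worsening
   transitions only;
4. the occupancy takes one matrix step; new deaths are recorded by sex;
5. mass on treatment at an EDSS above the discontinuation threshold is
   moved off treatment (irreversibly — mass that later improves stays
   off DMT);
6. the cohort ages by one year.

Off-DMT strata evolve under the "none" effect (natural history) and
accrue no drug cost downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import (
    N_EDSS,
    MortalityModel,
    NaturalHistory,
    ParameterSet,
    TreatmentEffect,
    apply_hazard_ratio,
)
from .scenarios import ScenarioSpec, active_treatment

__all__ = [
    "ON_DMT",
    "OFF_DMT",
    "MALE",
    "FEMALE",
    "SEX_LABELS",
    "STATUS_LABELS",
    "CohortState",
    "CohortTrace",
    "build_cycle_matrix",
    "apply_discontinuation",
    "expected_relapses",
    "run_scenario",
]

ON_DMT, OFF_DMT = 0, 1
MALE, FEMALE = 0, 1
STATUS_LABELS = ("on_dmt", "off_dmt")
SEX_LABELS = ("male", "female")

MASS_TOL = 1e-10


@dataclass
class CohortState:
    """Cohort mass at one cycle boundary.

    ``occupancy`` has shape (10, 2, 2): EDSS x treatment status x sex.
    ``dead_mass`` plus total occupancy is 1.
    """

    occupancy: np.ndarray
    dead_mass: float
    current_age: float
    cycle_index: int

    def living_mass(self) -> float:
        return float(self.occupancy.sum())

    def edss_distribution(self) -> np.ndarray:
        """Living mass per EDSS state (summed over status and sex)."""
        return self.occupancy.sum(axis=(1, 2))

    def check_conservation(self) -> None:
        total = self.living_mass() + self.dead_mass
        if abs(total - 1.0) > MASS_TOL:
            raise AssertionError(
                f"mass not conserved at cycle {self.cycle_index}: total {total!r}"
            )


@dataclass
class CohortTrace:
    """Full per-cycle history of one scenario run.

    ``states`` has ``horizon + 1`` entries (cycle boundaries 0..horizon).
    Per-cycle series (length ``horizon``) are indexed by the cycle during
    which they accrue: ``new_deaths_by_sex[t]`` are deaths between
    boundaries t and t+1, ``expected_relapses_per_cycle[t]`` the relapses
    during that year, ``active_treatment_per_cycle[t]`` the therapy in
    force.
    """

    states: list[CohortState]
    new_deaths_by_sex: np.ndarray  # (horizon, 2)
    expected_relapses_per_cycle: np.ndarray  # (horizon,)
    active_treatment_per_cycle: list[str]
    scenario_label: str = ""

    @property
    def horizon(self) -> int:
        return len(self.states) - 1

    @property
    def new_deaths_per_cycle(self) -> np.ndarray:
        return self.new_deaths_by_sex.sum(axis=1)

    @property
    def start_age(self) -> float:
        return self.states[0].current_age


def _treated_edss_matrix(nh: NaturalHistory, effect: TreatmentEffect) -> np.ndarray:
    """10x10 EDSS transition matrix with the treatment HR on worsening moves.

    Only worsening entries (column > row) are hazard-scaled; the freed
    probability mass is added to the stay entry, leaving improvement
    probabilities at their natural-history values.
    """
    P = nh.transition_matrix.copy()
    hr = effect.hr_progression
    if hr == 1.0:
        return P
    for i in range(N_EDSS - 1):
        worsen = P[i, i + 1 :].copy()
        adjusted = apply_hazard_ratio(worsen, hr)
        P[i, i + 1 :] = adjusted
        P[i, i] += worsen.sum() - adjusted.sum()
        if P[i, i] < 0:
            # only reachable with hr > 1 on rows whose worsening mass
            # nearly exhausts the stay probability
            raise ValueError(
                f"hazard ratio {hr} over-inflates worsening from EDSS {i}: "
                "stay probability would become negative"
            )
    return P


def build_cycle_matrix(
    nh: NaturalHistory,
    effect: TreatmentEffect,
    mortality: MortalityModel,
    age: float,
    sex: int,
) -> np.ndarray:
    """11x11 one-cycle transition matrix (states: EDSS 0-9, then dead).

    The death column is the age/sex background probability times the MS
    hazard ratio (capped at 1), identical for every living state; EDSS
    moves are the (treatment-adjusted) natural-history probabilities
    rescaled to the surviving fraction; the dead row is absorbing.
    """
    q = min(1.0, mortality.death_probability(age, sex) * mortality.ms_hazard_ratio)
    M = np.zeros((N_EDSS + 1, N_EDSS + 1))
    M[:N_EDSS, :N_EDSS] = _treated_edss_matrix(nh, effect) * (1.0 - q)
    M[:N_EDSS, N_EDSS] = q
    M[N_EDSS, N_EDSS] = 1.0
    row_sums = M.sum(axis=1)
    assert np.all(np.abs(row_sums - 1.0) < 1e-9), "cycle matrix rows must sum to 1"
    return M


def apply_discontinuation(state: CohortState, threshold: int) -> CohortState:
    """Move on-DMT mass at EDSS strictly above ``threshold`` off DMT.

    Total mass is unchanged; the operation is idempotent.
    """
    occ = state.occupancy.copy()
    above = slice(threshold + 1, N_EDSS)
    occ[above, OFF_DMT, :] += occ[above, ON_DMT, :]
    occ[above, ON_DMT, :] = 0.0
    return CohortState(
        occupancy=occ,
        dead_mass=state.dead_mass,
        current_age=state.current_age,
        cycle_index=state.cycle_index,
    )


def expected_relapses(
    state: CohortState, arr: np.ndarray, effect: TreatmentEffect
) -> float:
    """Expected relapses per patient over one cycle from this state.

    On-DMT mass relapses at ``arr(EDSS) * rr_relapse`` of the active
    effect; off-DMT mass at the untreated rate.  The dead accrue none.
    """
    arr = np.asarray(arr, dtype=float)
    on = state.occupancy[:, ON_DMT, :].sum(axis=1)
    off = state.occupancy[:, OFF_DMT, :].sum(axis=1)
    return float(on @ arr * effect.rr_relapse + off @ arr)


def _initial_state(params: ParameterSet) -> CohortState:
    occ = np.zeros((N_EDSS, 2, 2))
    dist = params.baseline.full_distribution()
    mf = params.baseline.male_fraction
    occ[:, ON_DMT, MALE] = dist * mf
    occ[:, ON_DMT, FEMALE] = dist * (1.0 - mf)
    return CohortState(
        occupancy=occ,
        dead_mass=0.0,
        current_age=params.baseline.start_age,
        cycle_index=0,
    )


def run_scenario(params: ParameterSet, scenario: ScenarioSpec) -> CohortTrace:
    """Advance the cohort over the scenario horizon and record the trace."""
    for name in scenario.treatment_names():
        params.treatment(name)  # raises on unknown treatment
    nh = params.natural_history
    mortality = params.mortality
    threshold = params.economics.discontinuation_edss_threshold
    horizon = scenario.horizon

    state = _initial_state(params)
    states = [state]
    deaths = np.zeros((horizon, 2))
    relapses = np.zeros(horizon)
    active: list[str] = []

    for t in range(horizon):
        name = active_treatment(scenario, t)
        effect_on = params.treatment(name)
        effect_off = params.treatment("none")
        active.append(name)

        relapses[t] = expected_relapses(state, nh.arr_by_edss, effect_on)

        age = math.floor(state.current_age)
        new_occ = np.zeros_like(state.occupancy)
        for sex in (MALE, FEMALE):
            q = min(
                1.0,
                mortality.death_probability(age, sex) * mortality.ms_hazard_ratio,
            )
            for status, eff in ((ON_DMT, effect_on), (OFF_DMT, effect_off)):
                mass = state.occupancy[:, status, sex]
                if not mass.any():
                    continue
                deaths[t, sex] += mass.sum() * q
                P = _treated_edss_matrix(nh, eff)
                new_occ[:, status, sex] = (mass @ P) * (1.0 - q)

        state = CohortState(
            occupancy=new_occ,
            dead_mass=state.dead_mass + float(deaths[t].sum()),
            current_age=state.current_age + 1.0,
            cycle_index=t + 1,
        )
        state = apply_discontinuation(state, threshold)
        state.check_conservation()
        states.append(state)

    return CohortTrace(
        states=states,
        new_deaths_by_sex=deaths,
        expected_relapses_per_cycle=relapses,
        active_treatment_per_cycle=active,
        scenario_label=scenario.label,
    )
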