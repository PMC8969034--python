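"""Seeded synthetic model inputs.

Real parameterizations of this model (baseline trial cohort, the British
Columbia natural-history transition matrix, network-meta-analysis effect
estimates, German life tables and per-EDSS cost studies) are not
redistributable here, so this module generates complete
:class:`~mscca.parameters.ParameterSet` objects with the same structure
and realistic magnitudes:

* baseline EDSS histogram on 0-6: a floor-discretized truncated normal
  calibrated so its mean hits the target (default 2.3, the early-RMS
  trial population), start age 36.3, 33% male;
* natural-history matrix: banded (most mass on stay and +-1 moves, small
  +-2 tails), with worsening exceeding improvement in every row below
  the top state, jittered per seed;
* ARR 0.7 for EDSS <= 4 and 0.5 above;
* effect estimates with the high-efficacy therapy (OMB) strictly
  superior to DMF and GA on both progression and relapses, and costlier;
* Gompertz-style life table with male excess mortality, remaining life
  expectancy computed from the same table, MS mortality hazard ratio 1.7;
* disability weights, direct costs, informal-care days and invalidity
  non-decreasing in EDSS; employment and full-time work non-increasing.

Generation is fully deterministic for a given seed; one named
``numpy.random.Generator`` carries all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .parameters import (
    N_EDSS,
    BaselineCohort,
    EconomicSettings,
    MortalityModel,
    NaturalHistory,
    ParameterSet,
    StateValuation,
    TreatmentEffect,
)

__all__ = ["SyntheticConfig", "generate_parameter_set", "generate_worked_fixture"]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic generator (defaults emulate the study cohort)."""

    seed: int = 0
    target_mean_edss: float = 2.3
    target_sd_edss: float = 1.2
    start_age: float = 36.3
    male_fraction: float = 0.33
    arr_low_edss: float = 0.7  # EDSS <= 4
    arr_high_edss: float = 0.5  # EDSS > 4
    hr_omb: float = 0.41
    hr_dmf: float = 0.73
    hr_ga: float = 0.85
    cost_scale: float = 1.0

    def validate(self) -> list[str]:
        errs = []
        if not (0.0 < self.target_mean_edss < 6.0):
            errs.append(
                f"target_mean_edss {self.target_mean_edss} infeasible on EDSS 0-6"
            )
        if self.target_sd_edss <= 0:
            errs.append("target_sd_edss must be positive")
        if not (0.0 <= self.male_fraction <= 1.0):
            errs.append("male_fraction must lie in [0, 1]")
        if self.arr_low_edss < 0 or self.arr_high_edss < 0:
            errs.append("relapse rates must be non-negative")
        if not (0 < self.hr_omb < self.hr_dmf <= self.hr_ga):
            errs.append(
                "hazard ratios must satisfy 0 < hr_omb < hr_dmf <= hr_ga, got "
                f"{self.hr_omb}, {self.hr_dmf}, {self.hr_ga}"
            )
        if self.cost_scale <= 0:
            errs.append("cost_scale must be positive")
        if self.start_age <= 0:
            errs.append("start_age must be positive")
        return errs


# ---------------------------------------------------------------------------
# baseline EDSS histogram
# ---------------------------------------------------------------------------

def _discretized_truncnorm(mu: float, sd: float) -> np.ndarray:
    """Floor-discretized normal truncated to [0, 7), normalized over EDSS 0-6.

    Flooring matches the model convention that intermediate EDSS values
    are rounded down.
    """
    edges = np.arange(8, dtype=float)
    cdf = norm.cdf((edges - mu) / sd)
    p = np.diff(cdf)
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate baseline distribution")
    return p / total


def _baseline_distribution(target_mean: float, sd: float) -> np.ndarray:
    """Calibrate the continuous mean so the discretized mean hits the target."""
    k = np.arange(7)

    def gap(mu: float) -> float:
        return float(_discretized_truncnorm(mu, sd) @ k) - target_mean

    mu = brentq(gap, -2.0, 9.0, xtol=1e-12)
    return _discretized_truncnorm(mu, sd)


# ---------------------------------------------------------------------------
# natural history
# ---------------------------------------------------------------------------

# per-row base band probabilities (jittered per seed): most patients stay,
# worsening dominates improvement, small two-step tails
_BAND_BASE = {+1: 0.17, +2: 0.03, -1: 0.06, -2: 0.01}


def _natural_history_matrix(rng: np.random.Generator) -> np.ndarray:
    P = np.zeros((N_EDSS, N_EDSS))
    for i in range(N_EDSS):
        row = np.zeros(N_EDSS)
        for step, base in _BAND_BASE.items():
            j = i + step
            p = base * rng.uniform(0.85, 1.15)
            if 0 <= j < N_EDSS:
                row[j] += p
            else:
                # fold out-of-range moves into the nearest feasible move
                jn = min(max(j, 0), N_EDSS - 1)
                if jn != i:
                    row[jn] += p
        if i == N_EDSS - 1:
            # top state cannot worsen; keep a token improvement probability
            row[:] = 0.0
            row[i - 1] = 0.03 * rng.uniform(0.85, 1.15)
        row[i] = 1.0 - row.sum()
        P[i] = row
    return P


def _arr_by_edss(cfg: SyntheticConfig) -> np.ndarray:
    arr = np.full(N_EDSS, cfg.arr_low_edss)
    arr[5:] = cfg.arr_high_edss  # EDSS > 4
    return arr


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------

_MAX_AGE = 110
# Gompertz q(age) = a * exp(b * age); male excess mortality via larger a
_GOMPERTZ_B = 0.093
_GOMPERTZ_A = {0: 3.2e-5, 1: 1.7e-5}  # male, female


def _life_table() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ages = np.arange(_MAX_AGE + 1)
    q = np.zeros((len(ages), 2))
    for sex, a in _GOMPERTZ_A.items():
        q[:, sex] = np.minimum(1.0, a * np.exp(_GOMPERTZ_B * ages))
    q[-1] = 1.0  # close the table
    # curtate remaining life expectancy from the same table
    ex = np.zeros_like(q)
    for sex in (0, 1):
        # backwards recursion: e(x) = (1 - q(x)) * (1 + e(x+1))
        for i in range(len(ages) - 1, -1, -1):
            nxt = ex[i + 1, sex] if i + 1 < len(ages) else 0.0
            ex[i, sex] = (1.0 - q[i, sex]) * (1.0 + nxt)
    return ages, q, ex


# ---------------------------------------------------------------------------
# per-EDSS valuations (annual EUR, days, proportions); EDSS 0..9
# ---------------------------------------------------------------------------

# Annual EUR per patient by EDSS.  Levels around EDSS 2-3 are anchored so
# that a 10-year discounted accumulation on an early-RMS trajectory lands
# near published German per-category sums; severity gradients (mild to
# bedridden roughly 3-10x, informal care steeper) follow the MS
# cost-of-illness literature.
_DIRECT_COST_BASE = {
    "inpatient_care": [800, 1000, 1400, 1900, 2600, 3500, 4600, 5800, 7200, 8800],
    "day_care_admissions": [70, 90, 120, 160, 220, 300, 400, 520, 660, 820],
    "consultations": [900, 1000, 1100, 1250, 1450, 1700, 2000, 2300, 2650, 3000],
    "tests_investigations": [300, 310, 325, 340, 360, 380, 400, 420, 440, 460],
    "other_medications": [400, 480, 580, 720, 900, 1120, 1400, 1750, 2150, 2600],
    "community_social_services": [150, 250, 420, 700, 1150, 1900, 3100, 5000, 7800, 11500],
    "investments_equipment_aids": [150, 230, 360, 560, 850, 1300, 1950, 2900, 4200, 5900],
    "informal_care": [400, 700, 1200, 2000, 3300, 5400, 8800, 14000, 21500, 31000],
}
_DISABILITY_WEIGHT_BASE = [0.03, 0.06, 0.10, 0.15, 0.21, 0.28, 0.37, 0.47, 0.58, 0.70]
_INFORMAL_DAYS_BASE = [4, 7, 12, 20, 33, 54, 88, 140, 215, 310]
_EMPLOYED_BASE = [0.78, 0.72, 0.65, 0.57, 0.48, 0.38, 0.28, 0.18, 0.10, 0.04]
_FULLTIME_BASE = [0.50, 0.45, 0.39, 0.32, 0.25, 0.18, 0.12, 0.07, 0.03, 0.01]
_INVALIDITY_BASE = [0.10, 0.16, 0.24, 0.34, 0.45, 0.56, 0.67, 0.77, 0.85, 0.92]
# short-term absence tracks employment (declines with EDSS); long-term
# absence/invalidity/early-retirement costs grow steeply with EDSS
_SHORT_ABSENCE_BASE = [850, 800, 730, 640, 540, 430, 320, 220, 130, 60]
_LONG_ABSENCE_BASE = [4500, 6200, 8500, 11500, 15500, 20500, 26500, 33500, 41500, 50500]


def _valuation(rng: np.random.Generator, cost_scale: float) -> StateValuation:
    # one multiplicative jitter factor per series keeps every monotonicity
    # constraint intact for any seed
    def jitter() -> float:
        return float(rng.uniform(0.92, 1.08))

    direct = {
        cat: np.asarray(base, dtype=float) * cost_scale * jitter()
        for cat, base in _DIRECT_COST_BASE.items()
    }
    return StateValuation(
        disability_weight=np.minimum(
            1.0, np.asarray(_DISABILITY_WEIGHT_BASE) * rng.uniform(0.95, 1.05)
        ),
        direct_costs=direct,
        informal_care_days=np.asarray(_INFORMAL_DAYS_BASE, dtype=float) * jitter(),
        employed_fraction=np.asarray(_EMPLOYED_BASE) * rng.uniform(0.95, 1.0),
        fulltime_fraction=np.asarray(_FULLTIME_BASE) * rng.uniform(0.95, 1.0),
        invalidity_fraction=np.minimum(
            1.0, np.asarray(_INVALIDITY_BASE) * rng.uniform(0.95, 1.05)
        ),
        short_term_absence_cost=np.asarray(_SHORT_ABSENCE_BASE, dtype=float)
        * cost_scale
        * jitter(),
        long_term_absence_cost=np.asarray(_LONG_ABSENCE_BASE, dtype=float)
        * cost_scale
        * jitter(),
    )


# annual drug prices (EUR); the high-efficacy therapy carries a loading-dose
# premium in its first year and stays the most expensive
_DRUG_PRICES = {
    "OMB": (20000.0, 18000.0),
    "DMF": (13000.0, 13000.0),
    "GA": (9000.0, 9000.0),
}
_RR_RELAPSE = {"OMB": 0.25, "DMF": 0.53, "GA": 0.66}


def generate_parameter_set(config: SyntheticConfig | None = None) -> ParameterSet:
    """Build a complete, validated ParameterSet from a seeded config."""
    cfg = config or SyntheticConfig()
    errs = cfg.validate()
    if errs:
        from .parameters import ParameterError

        raise ParameterError(errs)
    rng = np.random.default_rng(cfg.seed)

    baseline = BaselineCohort(
        edss_distribution=_baseline_distribution(cfg.target_mean_edss, cfg.target_sd_edss),
        start_age=cfg.start_age,
        male_fraction=cfg.male_fraction,
        cohort_size=1000.0,
    )
    nh = NaturalHistory(
        transition_matrix=_natural_history_matrix(rng),
        arr_by_edss=_arr_by_edss(cfg),
    )
    hrs = {"OMB": cfg.hr_omb, "DMF": cfg.hr_dmf, "GA": cfg.hr_ga}
    treatments = {
        name: TreatmentEffect(
            name=name,
            hr_progression=hrs[name],
            rr_relapse=_RR_RELAPSE[name],
            annual_drug_cost_year1=_DRUG_PRICES[name][0] * cfg.cost_scale,
            annual_drug_cost_subsequent=_DRUG_PRICES[name][1] * cfg.cost_scale,
        )
        for name in ("OMB", "DMF", "GA")
    }
    treatments["none"] = TreatmentEffect(name="none")

    ages, q, ex = _life_table()
    mortality = MortalityModel(
        ages=ages, death_prob=q, life_expectancy=ex, ms_hazard_ratio=1.7
    )

    ps = ParameterSet(
        baseline=baseline,
        natural_history=nh,
        treatments=treatments,
        mortality=mortality,
        valuation=_valuation(rng, cfg.cost_scale),
        economics=EconomicSettings(),
    )
    return ps.require_valid()


def generate_worked_fixture() -> ParameterSet:
    """Tiny hand-written fixture with round numbers for oracle tests.

    The dynamics are confined to EDSS 0-2 plus death (rows 3-9 are inert
    and never receive mass), so the whole model can be unrolled by hand:

    * baseline: 0.5 / 0.3 / 0.2 on EDSS 0/1/2, age 40, 40% male
    * transitions: row 0 = (0.80, 0.15, 0.05); row 1 = (0.05, 0.75, 0.20);
      row 2 = (0.00, 0.10, 0.90); rows 3-9 identity
    * ARR: 0.6 / 0.5 / 0.4 on EDSS 0/1/2, zero elsewhere
    * treatments: OMB hr 0.5, rr 0.5, prices 12000/10000;
      DMF hr 0.7, rr 0.7, price 8000; GA hr 0.9, rr 0.9, price 6000
    * mortality: flat annual death probability 0.02 (male) / 0.01
      (female), MS hazard ratio 1.0
    * disability weight 0.1*EDSS; direct costs, days and productivity
      linear in EDSS (see the source); discounting 3%, relapse cost 2662
    """
    P = np.eye(N_EDSS)
    P[0, :3] = [0.80, 0.15, 0.05]
    P[1, :3] = [0.05, 0.75, 0.20]
    P[2, :3] = [0.00, 0.10, 0.90]
    arr = np.zeros(N_EDSS)
    arr[:3] = [0.6, 0.5, 0.4]

    ages = np.arange(_MAX_AGE + 1)
    q = np.zeros((len(ages), 2))
    q[:, 0], q[:, 1] = 0.02, 0.01
    q[-1] = 1.0
    ex = np.zeros_like(q)
    for sex in (0, 1):
        for i in range(len(ages) - 1, -1, -1):
            nxt = ex[i + 1, sex] if i + 1 < len(ages) else 0.0
            ex[i, sex] = (1.0 - q[i, sex]) * (1.0 + nxt)

    i = np.arange(N_EDSS, dtype=float)
    valuation = StateValuation(
        disability_weight=np.minimum(0.9, 0.1 * i),
        direct_costs={
            "inpatient_care": 1000.0 + 500.0 * i,
            "day_care_admissions": 100.0 * i,
            "consultations": 500.0 + 100.0 * i,
            "tests_investigations": 200.0 + 10.0 * i,
            "other_medications": 300.0 + 50.0 * i,
            "community_social_services": 150.0 * i,
            "investments_equipment_aids": 120.0 * i,
            "informal_care": 400.0 * i,
        },
        informal_care_days=10.0 * i,
        employed_fraction=np.maximum(0.0, 0.8 - 0.08 * i),
        fulltime_fraction=np.maximum(0.0, 0.5 - 0.05 * i),
        invalidity_fraction=np.minimum(1.0, 0.05 + 0.09 * i),
        short_term_absence_cost=np.maximum(0.0, 500.0 - 50.0 * i),
        long_term_absence_cost=2000.0 * i,
    )

    ps = ParameterSet(
        baseline=BaselineCohort(
            edss_distribution=np.array([0.5, 0.3, 0.2, 0, 0, 0, 0], dtype=float),
            start_age=40.0,
            male_fraction=0.4,
            cohort_size=100.0,
        ),
        natural_history=NaturalHistory(transition_matrix=P, arr_by_edss=arr),
        treatments={
            "OMB": TreatmentEffect("OMB", 0.5, 0.5, 12000.0, 10000.0),
            "DMF": TreatmentEffect("DMF", 0.7, 0.7, 8000.0, 8000.0),
            "GA": TreatmentEffect("GA", 0.9, 0.9, 6000.0, 6000.0),
            "none": TreatmentEffect("none"),
        },
        mortality=MortalityModel(
            ages=ages, death_prob=q, life_expectancy=ex, ms_hazard_ratio=1.0
        ),
        valuation=valuation,
        economics=EconomicSettings(),
    )
    return ps.require_valid()
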