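"""Model inputs: domain types, validation, file I/O, and probability transforms.

The simulator propagates a cohort of relapsing-MS patients over integer
EDSS states 0-9 (EDSS 10, death from MS, is folded into the absorbing
dead state together with background mortality).  Everything the engine
needs is collected in a single :class:`ParameterSet`:

* ``baseline`` -- the starting cohort (EDSS histogram over 0-6, mean age,
  sex mix),
* ``natural_history`` -- the untreated annual EDSS transition matrix and
  state-dependent annualized relapse rates (ARR),
* ``treatments`` -- per-therapy hazard ratios on disability worsening
  (from 6-month confirmed disability progression), rate ratios on
  relapses, and the drug price schedule,
* ``mortality`` -- an age/sex life table plus a single MS mortality
  hazard ratio applied uniformly to all living states,
* ``valuation`` -- per-EDSS disability weights, direct-cost categories,
  informal-care days and productivity inputs,
* ``economics`` -- discount rates, relapse unit cost, retirement age,
  horizon and the treatment-discontinuation EDSS threshold.

Validation is collective: ``ParameterSet.validate()`` returns *every*
violation found, and the file loader raises one error listing all of
them, so a malformed input file can be fixed in one pass.

All currency values are a single abstract unit (documented as EUR);
no conversion or inflation machinery is provided.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "N_EDSS",
    "BASELINE_MAX_EDSS",
    "DIRECT_COST_CATEGORIES",
    "INDIRECT_COST_CATEGORIES",
    "SCHEMA_VERSION",
    "NO_TREATMENT_NAME",
    "BaselineCohort",
    "NaturalHistory",
    "TreatmentEffect",
    "MortalityModel",
    "StateValuation",
    "EconomicSettings",
    "ParameterSet",
    "ParameterError",
    "prob_to_rate",
    "rate_to_prob",
    "apply_hazard_ratio",
    "load_parameter_set",
    "save_parameter_set",
    "parameter_set_to_dict",
]

#: number of living EDSS states modelled (integer EDSS 0..9)
N_EDSS = 10
#: highest EDSS present in the baseline cohort
BASELINE_MAX_EDSS = 6
#: row-sum tolerance accepted on load; rows within it are renormalized
ROW_SUM_TOLERANCE = 1e-9

DIRECT_COST_CATEGORIES = (
    "inpatient_care",
    "day_care_admissions",
    "consultations",
    "tests_investigations",
    "other_medications",
    "community_social_services",
    "investments_equipment_aids",
    "informal_care",
)
INDIRECT_COST_CATEGORIES = (
    "short_term_absence",
    "long_term_absence",
)

SCHEMA_VERSION = 1

#: name of the pseudo-treatment used for off-DMT strata
NO_TREATMENT_NAME = "none"


class ParameterError(ValueError):
    """Raised when a parameter file or ParameterSet is invalid.

    ``errors`` carries every violation found, not just the first.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "invalid parameters:\n" + "\n".join(f"  - {e}" for e in self.errors)
        )


# ---------------------------------------------------------------------------
# elementary probability / hazard transforms
# ---------------------------------------------------------------------------

def prob_to_rate(p, t: float = 1.0):
    """Convert a probability over duration ``t`` years to a constant rate.

    Assumes an exponential waiting time: ``r = -ln(1 - p) / t``.
    Inverse of :func:`rate_to_prob`.
    """
    p = np.asarray(p, dtype=float)
    if t <= 0:
        raise ValueError(f"duration must be positive, got {t}")
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("probability must lie in [0, 1)")
    out = -np.log1p(-p) / t
    return float(out) if out.ndim == 0 else out


def rate_to_prob(r, t: float = 1.0):
    """Convert a constant rate per year to a probability over ``t`` years.

    ``p = 1 - exp(-r t)``.  Inverse of :func:`prob_to_rate`.
    """
    r = np.asarray(r, dtype=float)
    if t <= 0:
        raise ValueError(f"duration must be positive, got {t}")
    if np.any(r < 0):
        raise ValueError("rate must be non-negative")
    out = -np.expm1(-r * t)
    return float(out) if out.ndim == 0 else out


def apply_hazard_ratio(p, hr: float):
    """Apply a hazard ratio to a per-cycle transition probability.

    Works on the complementary-log scale, ``p' = 1 - (1 - p)**hr``,
    i.e. the per-cycle hazard is multiplied by ``hr``.  This is the
    standard health-economics convention for carrying a hazard ratio
    from a time-to-event analysis onto discrete-time transition
    probabilities; it reduces to the identity at ``hr = 1`` and maps
    0 to 0 for any ``hr``.
    """
    if hr <= 0:
        raise ValueError(f"hazard ratio must be positive, got {hr}")
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probability must be non-negative")
    if hr == 1.0:
        if np.any(p > 1):
            raise ValueError("probability must lie in [0, 1]")
        return float(p) if p.ndim == 0 else p.copy()
    if np.any(p >= 1):
        raise ValueError("cannot rescale a degenerate probability (p >= 1)")
    out = -np.expm1(hr * np.log1p(-p))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class BaselineCohort:
    """Starting cohort: EDSS histogram over 0-6, mean age, sex mix.

    ``cohort_size`` is a reporting scale only; all engine outputs are
    per patient.
    """

    edss_distribution: np.ndarray  # length 7, EDSS 0..6
    start_age: float
    male_fraction: float
    cohort_size: float = 1000.0

    def __post_init__(self):
        self.edss_distribution = _as_array(self.edss_distribution)

    def validate(self) -> list[str]:
        errs = []
        d = self.edss_distribution
        if d.shape != (BASELINE_MAX_EDSS + 1,):
            errs.append(
                f"baseline.edss_distribution must have length "
                f"{BASELINE_MAX_EDSS + 1} (EDSS 0-{BASELINE_MAX_EDSS}), "
                f"got shape {d.shape}"
            )
            return errs
        if np.any(d < 0):
            errs.append("baseline.edss_distribution has negative entries")
        if abs(d.sum() - 1.0) > 1e-12:
            errs.append(
                f"baseline.edss_distribution sums to {d.sum()!r}, expected 1"
            )
        if not (0.0 <= self.male_fraction <= 1.0):
            errs.append(f"baseline.male_fraction {self.male_fraction} not in [0, 1]")
        if not self.start_age > 0:
            errs.append(f"baseline.start_age must be positive, got {self.start_age}")
        if self.cohort_size <= 0:
            errs.append("baseline.cohort_size must be positive")
        return errs

    def full_distribution(self) -> np.ndarray:
        """Histogram padded to all modelled EDSS states 0-9."""
        full = np.zeros(N_EDSS)
        full[: len(self.edss_distribution)] = self.edss_distribution
        return full

    def mean_edss(self) -> float:
        return float(self.edss_distribution @ np.arange(len(self.edss_distribution)))


@dataclass
class NaturalHistory:
    """Untreated annual EDSS transition matrix and per-state relapse rates."""

    transition_matrix: np.ndarray  # (10, 10) row-stochastic
    arr_by_edss: np.ndarray  # (10,) relapses per patient-year

    def __post_init__(self):
        self.transition_matrix = _as_array(self.transition_matrix)
        self.arr_by_edss = _as_array(self.arr_by_edss)

    def validate(self) -> list[str]:
        errs = []
        m = self.transition_matrix
        if m.shape != (N_EDSS, N_EDSS):
            errs.append(
                f"natural_history.transition_matrix must be {N_EDSS}x{N_EDSS}, "
                f"got {m.shape}"
            )
            return errs
        if np.any(m < 0) or np.any(m > 1):
            errs.append("natural_history.transition_matrix entries outside [0, 1]")
        sums = m.sum(axis=1)
        for i, s in enumerate(sums):
            if abs(s - 1.0) > 1e-12:
                errs.append(
                    f"natural_history.transition_matrix row {i} sums to {s!r}, "
                    f"expected 1"
                )
        if self.arr_by_edss.shape != (N_EDSS,):
            errs.append(
                f"natural_history.arr_by_edss must have length {N_EDSS}, "
                f"got shape {self.arr_by_edss.shape}"
            )
        elif np.any(self.arr_by_edss < 0):
            errs.append("natural_history.arr_by_edss has negative rates")
        return errs


@dataclass
class TreatmentEffect:
    """Treatment modifiers and price schedule for one therapy.

    ``hr_progression`` multiplies the hazard of every EDSS-worsening
    transition (derived from 6-month confirmed disability progression);
    ``rr_relapse`` multiplies the annualized relapse rate.  Drug prices
    distinguish the first year on the therapy (loading doses) from
    subsequent years; an optional explicit second-year price
    ``annual_drug_cost_year2`` overrides the subsequent-year price in
    the second year only (it defaults to the subsequent price).
    """

    name: str
    hr_progression: float = 1.0
    rr_relapse: float = 1.0
    annual_drug_cost_year1: float = 0.0
    annual_drug_cost_subsequent: float = 0.0
    annual_drug_cost_year2: float | None = None

    def validate(self) -> list[str]:
        errs = []
        p = f"treatments[{self.name}]"
        if self.hr_progression <= 0:
            errs.append(f"{p}.hr_progression must be positive")
        if self.rr_relapse <= 0:
            errs.append(f"{p}.rr_relapse must be positive")
        for fld in ("annual_drug_cost_year1", "annual_drug_cost_subsequent"):
            if getattr(self, fld) < 0:
                errs.append(f"{p}.{fld} must be non-negative")
        if self.annual_drug_cost_year2 is not None and self.annual_drug_cost_year2 < 0:
            errs.append(f"{p}.annual_drug_cost_year2 must be non-negative")
        if self.name == NO_TREATMENT_NAME:
            if self.hr_progression != 1.0 or self.rr_relapse != 1.0:
                errs.append(f"{p}: the '{NO_TREATMENT_NAME}' treatment must have hr=rr=1")
            if (
                self.annual_drug_cost_year1 != 0.0
                or self.annual_drug_cost_subsequent != 0.0
            ):
                errs.append(f"{p}: the '{NO_TREATMENT_NAME}' treatment must be free")
        return errs

    def drug_cost(self, years_since_start: int) -> float:
        """Annual price in the given year of use (0 = first year)."""
        if years_since_start < 0:
            raise ValueError("years_since_start must be >= 0")
        if years_since_start == 0:
            return self.annual_drug_cost_year1
        if years_since_start == 1 and self.annual_drug_cost_year2 is not None:
            return self.annual_drug_cost_year2
        return self.annual_drug_cost_subsequent


#: effect applied to off-DMT strata when no explicit "none" entry exists
NO_TREATMENT = TreatmentEffect(NO_TREATMENT_NAME)


@dataclass
class MortalityModel:
    """Background mortality and remaining life expectancy by age and sex.

    ``death_prob`` and ``life_expectancy`` are (n_ages, 2) arrays with
    column 0 = male, column 1 = female, indexed by ``ages`` (consecutive
    integer years).  The single ``ms_hazard_ratio`` scales the background
    annual death probability identically for every living EDSS state.
    """

    ages: np.ndarray  # (n,) consecutive integers
    death_prob: np.ndarray  # (n, 2) male/female annual probability
    life_expectancy: np.ndarray  # (n, 2) remaining years
    ms_hazard_ratio: float = 1.7

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.death_prob = _as_array(self.death_prob)
        self.life_expectancy = _as_array(self.life_expectancy)

    def validate(self) -> list[str]:
        errs = []
        n = len(self.ages)
        if n == 0:
            return ["mortality: empty life table"]
        if np.any(np.diff(self.ages) != 1):
            errs.append("mortality.ages must be consecutive integers")
        for name, arr in (
            ("death_prob", self.death_prob),
            ("life_expectancy", self.life_expectancy),
        ):
            if arr.shape != (n, 2):
                errs.append(
                    f"mortality.{name} must have shape ({n}, 2), got {arr.shape}"
                )
                return errs
        if np.any(self.death_prob < 0) or np.any(self.death_prob > 1):
            errs.append("mortality.death_prob entries outside [0, 1]")
        if np.any(self.life_expectancy < 0):
            errs.append("mortality.life_expectancy has negative entries")
        if np.any(np.diff(self.life_expectancy, axis=0) > 1e-12):
            errs.append("mortality.life_expectancy must be non-increasing in age")
        if self.ms_hazard_ratio <= 0:
            errs.append("mortality.ms_hazard_ratio must be positive")
        return errs

    def _row(self, age: float) -> int:
        idx = int(np.floor(age)) - int(self.ages[0])
        if idx < 0 or idx >= len(self.ages):
            raise ValueError(
                f"age {age} outside life table range "
                f"[{self.ages[0]}, {self.ages[-1]}]"
            )
        return idx

    def death_probability(self, age: float, sex: int) -> float:
        """Background annual death probability at floor(age) for a sex (0=male)."""
        return float(self.death_prob[self._row(age), sex])

    def remaining_life_expectancy(self, age: float, sex: int) -> float:
        return float(self.life_expectancy[self._row(age), sex])


@dataclass
class StateValuation:
    """Per-EDSS disability weights, annual costs, and productivity inputs.

    All arrays are length 10 (EDSS 0-9).  ``direct_costs`` holds one
    annual-cost array per non-DMT direct category
    (:data:`DIRECT_COST_CATEGORIES`); the two indirect productivity-loss
    categories are per-state annual costs applied only below retirement
    age.
    """

    disability_weight: np.ndarray
    direct_costs: dict[str, np.ndarray]
    informal_care_days: np.ndarray
    employed_fraction: np.ndarray
    fulltime_fraction: np.ndarray
    invalidity_fraction: np.ndarray
    short_term_absence_cost: np.ndarray
    long_term_absence_cost: np.ndarray

    def __post_init__(self):
        self.disability_weight = _as_array(self.disability_weight)
        self.direct_costs = {k: _as_array(v) for k, v in self.direct_costs.items()}
        for fld in (
            "informal_care_days",
            "employed_fraction",
            "fulltime_fraction",
            "invalidity_fraction",
            "short_term_absence_cost",
            "long_term_absence_cost",
        ):
            setattr(self, fld, _as_array(getattr(self, fld)))

    def indirect_costs(self) -> dict[str, np.ndarray]:
        return {
            "short_term_absence": self.short_term_absence_cost,
            "long_term_absence": self.long_term_absence_cost,
        }

    def validate(self) -> list[str]:
        errs = []
        missing = set(DIRECT_COST_CATEGORIES) - set(self.direct_costs)
        extra = set(self.direct_costs) - set(DIRECT_COST_CATEGORIES)
        if missing:
            errs.append(f"valuation.direct_costs missing categories: {sorted(missing)}")
        if extra:
            errs.append(f"valuation.direct_costs unknown categories: {sorted(extra)}")

        def _check(name, arr, lo=0.0, hi=None):
            if arr.shape != (N_EDSS,):
                errs.append(f"valuation.{name} must have length {N_EDSS}")
                return
            if np.any(arr < lo) or (hi is not None and np.any(arr > hi)):
                rng = f"[{lo}, {hi}]" if hi is not None else f">= {lo}"
                errs.append(f"valuation.{name} entries outside {rng}")

        _check("disability_weight", self.disability_weight, 0.0, 1.0)
        for cat, arr in self.direct_costs.items():
            _check(f"direct_costs[{cat}]", arr)
        _check("informal_care_days", self.informal_care_days)
        _check("employed_fraction", self.employed_fraction, 0.0, 1.0)
        _check("fulltime_fraction", self.fulltime_fraction, 0.0, 1.0)
        _check("invalidity_fraction", self.invalidity_fraction, 0.0, 1.0)
        _check("short_term_absence_cost", self.short_term_absence_cost)
        _check("long_term_absence_cost", self.long_term_absence_cost)
        return errs


@dataclass
class EconomicSettings:
    """Discounting, relapse unit cost, retirement age, horizon, stopping rule."""

    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    annual_relapse_cost: float = 2662.0
    retirement_age: float = 67.0
    horizon_years: int = 10
    discontinuation_edss_threshold: int = 6

    def validate(self) -> list[str]:
        errs = []
        if self.discount_rate_costs < 0:
            errs.append("economics.discount_rate_costs must be >= 0")
        if self.discount_rate_effects < 0:
            errs.append("economics.discount_rate_effects must be >= 0")
        if self.annual_relapse_cost < 0:
            errs.append("economics.annual_relapse_cost must be >= 0")
        if self.horizon_years < 1:
            errs.append("economics.horizon_years must be >= 1")
        if not (0 <= self.discontinuation_edss_threshold <= N_EDSS - 1):
            errs.append(
                "economics.discontinuation_edss_threshold must be an EDSS in "
                f"0-{N_EDSS - 1}"
            )
        return errs


@dataclass
class ParameterSet:
    """Complete validated model inputs."""

    baseline: BaselineCohort
    natural_history: NaturalHistory
    treatments: dict[str, TreatmentEffect]
    mortality: MortalityModel
    valuation: StateValuation
    economics: EconomicSettings

    def validate(self) -> list[str]:
        errs = []
        errs += self.baseline.validate()
        errs += self.natural_history.validate()
        for name, t in self.treatments.items():
            if name != t.name:
                errs.append(f"treatments key {name!r} does not match name {t.name!r}")
            errs += t.validate()
        errs += self.mortality.validate()
        errs += self.valuation.validate()
        errs += self.economics.validate()
        return errs

    def require_valid(self) -> "ParameterSet":
        errs = self.validate()
        if errs:
            raise ParameterError(errs)
        return self

    def treatment(self, name: str) -> TreatmentEffect:
        if name == NO_TREATMENT_NAME and name not in self.treatments:
            return NO_TREATMENT
        try:
            return self.treatments[name]
        except KeyError:
            raise KeyError(
                f"unknown treatment {name!r}; available: {sorted(self.treatments)}"
            ) from None

    def copy(self) -> "ParameterSet":
        """Deep, independent copy (arrays are not shared)."""
        return _copy_dataclass(self)


def _copy_dataclass(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return type(obj)(
            **{
                f.name: _copy_dataclass(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            }
        )
    if isinstance(obj, dict):
        return {k: _copy_dataclass(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.copy()
    return obj


# ---------------------------------------------------------------------------
# file I/O
#
# Layout: one YAML config (scalars, baseline histogram, treatments) next to
# three CSV tables -- transitions.csv, life_table.csv, valuations.csv --
# referenced by relative path.  Plain dot-decimal numbers throughout.
# ---------------------------------------------------------------------------

_CONFIG_REQUIRED = {
    "schema_version",
    "baseline",
    "natural_history",
    "treatments",
    "mortality",
    "valuation",
    "economics",
}


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load a :class:`ParameterSet` from a YAML config (plus CSV tables).

    ``path`` may be the config file itself or a directory containing
    ``parameters.yaml``.  All schema and invariant violations found are
    reported together in a single :class:`ParameterError`.
    """
    path = Path(path)
    if path.is_dir():
        path = path / "parameters.yaml"
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParameterError(["config root must be a mapping"])

    errs: list[str] = []
    missing = _CONFIG_REQUIRED - set(cfg)
    if missing:
        raise ParameterError(
            [f"config missing required section: {k}" for k in sorted(missing)]
        )
    if cfg["schema_version"] != SCHEMA_VERSION:
        errs.append(
            f"unsupported schema_version {cfg['schema_version']!r} "
            f"(expected {SCHEMA_VERSION})"
        )

    base_dir = path.parent

    def _table(section: dict, key: str, label: str) -> pd.DataFrame | None:
        rel = section.get(key)
        if rel is None:
            errs.append(f"{label} missing table reference {key!r}")
            return None
        csv_path = base_dir / rel
        if not csv_path.exists():
            errs.append(f"{label}: table file not found: {csv_path}")
            return None
        return pd.read_csv(csv_path, float_precision="round_trip")

    def _get(section: Mapping, key: str, label: str, default=None, required=True):
        if key in section:
            return section[key]
        if required:
            errs.append(f"{label} missing field {key!r}")
        return default

    # baseline ------------------------------------------------------------
    b = cfg["baseline"]
    baseline = BaselineCohort(
        edss_distribution=np.asarray(
            _get(b, "edss_distribution", "baseline", default=[]), dtype=float
        ),
        start_age=float(_get(b, "start_age", "baseline", default=1.0)),
        male_fraction=float(_get(b, "male_fraction", "baseline", default=0.0)),
        cohort_size=float(b.get("cohort_size", 1000.0)),
    )

    # natural history -----------------------------------------------------
    nhs = cfg["natural_history"]
    tm = np.zeros((N_EDSS, N_EDSS))
    tdf = _table(nhs, "transitions", "natural_history")
    if tdf is not None:
        cols = [f"to_{j}" for j in range(N_EDSS)]
        missing_cols = [c for c in ["from_edss", *cols] if c not in tdf.columns]
        if missing_cols:
            errs.append(f"transitions.csv missing columns: {missing_cols}")
        elif len(tdf) != N_EDSS:
            errs.append(f"transitions.csv must have {N_EDSS} rows, got {len(tdf)}")
        else:
            tdf = tdf.sort_values("from_edss")
            tm = tdf[cols].to_numpy(dtype=float)
            # renormalize rows off by floating noise only; reject real defects
            sums = tm.sum(axis=1)
            for i, s in enumerate(sums):
                if abs(s - 1.0) <= ROW_SUM_TOLERANCE and s > 0:
                    tm[i] /= s
                elif abs(s - 1.0) > ROW_SUM_TOLERANCE:
                    errs.append(
                        f"transitions.csv row from_edss={i} sums to {s}, expected 1"
                    )
    nh = NaturalHistory(
        transition_matrix=tm,
        arr_by_edss=np.asarray(
            _get(nhs, "arr_by_edss", "natural_history", default=np.zeros(N_EDSS)),
            dtype=float,
        ),
    )

    # treatments ----------------------------------------------------------
    treatments: dict[str, TreatmentEffect] = {}
    for entry in cfg["treatments"]:
        name = _get(entry, "name", "treatments[]", default="?")
        y2 = entry.get("annual_drug_cost_year2")
        treatments[name] = TreatmentEffect(
            name=name,
            hr_progression=float(_get(entry, "hr_progression", f"treatments[{name}]", 1.0)),
            rr_relapse=float(_get(entry, "rr_relapse", f"treatments[{name}]", 1.0)),
            annual_drug_cost_year1=float(
                _get(entry, "annual_drug_cost_year1", f"treatments[{name}]", 0.0)
            ),
            annual_drug_cost_subsequent=float(
                _get(entry, "annual_drug_cost_subsequent", f"treatments[{name}]", 0.0)
            ),
            annual_drug_cost_year2=None if y2 is None else float(y2),
        )

    # mortality -----------------------------------------------------------
    ms = cfg["mortality"]
    ldf = _table(ms, "life_table", "mortality")
    if ldf is not None:
        lcols = [
            "age",
            "death_prob_male",
            "death_prob_female",
            "life_expectancy_male",
            "life_expectancy_female",
        ]
        missing_cols = [c for c in lcols if c not in ldf.columns]
        if missing_cols:
            errs.append(f"life_table.csv missing columns: {missing_cols}")
            ldf = None
    if ldf is not None:
        ldf = ldf.sort_values("age")
        mortality = MortalityModel(
            ages=ldf["age"].to_numpy(dtype=int),
            death_prob=ldf[["death_prob_male", "death_prob_female"]].to_numpy(float),
            life_expectancy=ldf[
                ["life_expectancy_male", "life_expectancy_female"]
            ].to_numpy(float),
            ms_hazard_ratio=float(_get(ms, "ms_hazard_ratio", "mortality", 1.0)),
        )
    else:
        mortality = MortalityModel(
            ages=np.arange(2), death_prob=np.zeros((2, 2)),
            life_expectancy=np.zeros((2, 2)), ms_hazard_ratio=1.0,
        )

    # valuation -----------------------------------------------------------
    vdf = _table(cfg["valuation"], "table", "valuation")
    vcols = [
        "edss",
        "disability_weight",
        *DIRECT_COST_CATEGORIES,
        "informal_care_days",
        "employed_fraction",
        "fulltime_fraction",
        "invalidity_fraction",
        "short_term_absence_cost",
        "long_term_absence_cost",
    ]
    if vdf is not None:
        missing_cols = [c for c in vcols if c not in vdf.columns]
        if missing_cols:
            errs.append(f"valuations.csv missing columns: {missing_cols}")
            vdf = None
        elif len(vdf) != N_EDSS:
            errs.append(f"valuations.csv must have {N_EDSS} rows, got {len(vdf)}")
            vdf = None
    if vdf is not None:
        vdf = vdf.sort_values("edss")
        valuation = StateValuation(
            disability_weight=vdf["disability_weight"].to_numpy(float),
            direct_costs={c: vdf[c].to_numpy(float) for c in DIRECT_COST_CATEGORIES},
            informal_care_days=vdf["informal_care_days"].to_numpy(float),
            employed_fraction=vdf["employed_fraction"].to_numpy(float),
            fulltime_fraction=vdf["fulltime_fraction"].to_numpy(float),
            invalidity_fraction=vdf["invalidity_fraction"].to_numpy(float),
            short_term_absence_cost=vdf["short_term_absence_cost"].to_numpy(float),
            long_term_absence_cost=vdf["long_term_absence_cost"].to_numpy(float),
        )
    else:
        z = np.zeros(N_EDSS)
        valuation = StateValuation(
            disability_weight=z, direct_costs={c: z for c in DIRECT_COST_CATEGORIES},
            informal_care_days=z, employed_fraction=z, fulltime_fraction=z,
            invalidity_fraction=z, short_term_absence_cost=z,
            long_term_absence_cost=z,
        )

    # economics -----------------------------------------------------------
    e = cfg["economics"]
    economics = EconomicSettings(
        discount_rate_costs=float(_get(e, "discount_rate_costs", "economics", 0.0)),
        discount_rate_effects=float(_get(e, "discount_rate_effects", "economics", 0.0)),
        annual_relapse_cost=float(_get(e, "annual_relapse_cost", "economics", 0.0)),
        retirement_age=float(e.get("retirement_age", 67.0)),
        horizon_years=int(_get(e, "horizon_years", "economics", 10)),
        discontinuation_edss_threshold=int(
            e.get("discontinuation_edss_threshold", 6)
        ),
    )

    ps = ParameterSet(
        baseline=baseline,
        natural_history=nh,
        treatments=treatments,
        mortality=mortality,
        valuation=valuation,
        economics=economics,
    )
    errs += ps.validate()
    if errs:
        raise ParameterError(errs)
    return ps


def save_parameter_set(ps: ParameterSet, directory: str | Path) -> Path:
    """Write a ParameterSet to ``directory`` in the standard layout.

    Returns the path of the YAML config.  The layout round-trips through
    :func:`load_parameter_set`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    tdf = pd.DataFrame(
        ps.natural_history.transition_matrix,
        columns=[f"to_{j}" for j in range(N_EDSS)],
    )
    tdf.insert(0, "from_edss", np.arange(N_EDSS))
    tdf.to_csv(directory / "transitions.csv", index=False, float_format="%.17g")

    ldf = pd.DataFrame(
        {
            "age": ps.mortality.ages,
            "death_prob_male": ps.mortality.death_prob[:, 0],
            "death_prob_female": ps.mortality.death_prob[:, 1],
            "life_expectancy_male": ps.mortality.life_expectancy[:, 0],
            "life_expectancy_female": ps.mortality.life_expectancy[:, 1],
        }
    )
    ldf.to_csv(directory / "life_table.csv", index=False, float_format="%.17g")

    v = ps.valuation
    vdf = pd.DataFrame({"edss": np.arange(N_EDSS)})
    vdf["disability_weight"] = v.disability_weight
    for c in DIRECT_COST_CATEGORIES:
        vdf[c] = v.direct_costs[c]
    vdf["informal_care_days"] = v.informal_care_days
    vdf["employed_fraction"] = v.employed_fraction
    vdf["fulltime_fraction"] = v.fulltime_fraction
    vdf["invalidity_fraction"] = v.invalidity_fraction
    vdf["short_term_absence_cost"] = v.short_term_absence_cost
    vdf["long_term_absence_cost"] = v.long_term_absence_cost
    vdf.to_csv(directory / "valuations.csv", index=False, float_format="%.17g")

    cfg = {
        "schema_version": SCHEMA_VERSION,
        "baseline": {
            "edss_distribution": [float(x) for x in ps.baseline.edss_distribution],
            "start_age": float(ps.baseline.start_age),
            "male_fraction": float(ps.baseline.male_fraction),
            "cohort_size": float(ps.baseline.cohort_size),
        },
        "natural_history": {
            "transitions": "transitions.csv",
            "arr_by_edss": [float(x) for x in ps.natural_history.arr_by_edss],
        },
        "treatments": [
            {
                "name": t.name,
                "hr_progression": float(t.hr_progression),
                "rr_relapse": float(t.rr_relapse),
                "annual_drug_cost_year1": float(t.annual_drug_cost_year1),
                "annual_drug_cost_subsequent": float(t.annual_drug_cost_subsequent),
                **(
                    {"annual_drug_cost_year2": float(t.annual_drug_cost_year2)}
                    if t.annual_drug_cost_year2 is not None
                    else {}
                ),
            }
            for t in ps.treatments.values()
        ],
        "mortality": {
            "life_table": "life_table.csv",
            "ms_hazard_ratio": float(ps.mortality.ms_hazard_ratio),
        },
        "valuation": {"table": "valuations.csv"},
        "economics": {
            "discount_rate_costs": float(ps.economics.discount_rate_costs),
            "discount_rate_effects": float(ps.economics.discount_rate_effects),
            "annual_relapse_cost": float(ps.economics.annual_relapse_cost),
            "retirement_age": float(ps.economics.retirement_age),
            "horizon_years": int(ps.economics.horizon_years),
            "discontinuation_edss_threshold": int(
                ps.economics.discontinuation_edss_threshold
            ),
        },
    }
    out = directory / "parameters.yaml"
    with open(out, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return out


def parameter_set_to_dict(ps: ParameterSet) -> dict:
    """Plain-type nested dict view, used for hashing and equality checks."""
    def conv(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {
                f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)
            }
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return conv(ps)
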