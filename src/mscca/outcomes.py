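"""Clinical, DALY, informal-care and productivity outcomes from a trace.

Snapshot outcomes (EDSS band shares, mean EDSS, employment shares) are
read at the end of the horizon and normalized over survivors, so the
four disability bands sum to 100%.  Accumulated outcomes follow the
start-of-cycle convention used everywhere in the model: years lived
with disability (YLD), informal-care days and relapse counts accrue
over cycles 0..horizon-1 from the state occupied at the start of each
year, while time-in-band counts the state at cycle boundaries
1..horizon so that a full-horizon stay equals the horizon length.

DALY components are discounted at the effects rate; time in band,
relapse counts and informal-care days are reported undiscounted, in
their natural units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import CohortTrace
from .parameters import MortalityModel, ParameterSet, StateValuation

__all__ = [
    "EDSS_BANDS",
    "OutcomeReport",
    "edss_band_shares",
    "mean_edss",
    "years_in_band",
    "compute_yll",
    "compute_yld",
    "total_relapses",
    "productivity_and_informal_care",
    "build_outcome_report",
]

#: Table-style disability bands over integer EDSS states
EDSS_BANDS: dict[str, tuple[int, ...]] = {
    "edss_0_3": (0, 1, 2, 3),  # no or mild disability
    "edss_4_6": (4, 5, 6),  # walking aid
    "edss_7": (7,),  # wheelchair
    "edss_8_9": (8, 9),  # bedridden
}
#: derived immobility band (wheelchair + bedridden)
IMMOBILE_BAND = (7, 8, 9)


def _living_distribution(trace: CohortTrace, year: int) -> np.ndarray:
    if not (0 <= year <= trace.horizon):
        raise ValueError(f"year {year} outside trace horizon [0, {trace.horizon}]")
    return trace.states[year].edss_distribution()


def edss_band_shares(trace: CohortTrace, year: int | None = None) -> dict[str, float]:
    """Living occupancy shares per disability band at a cycle boundary.

    Normalized over survivors; includes the derived ``edss_7_9``
    immobility band (sum of wheelchair and bedridden shares).
    """
    year = trace.horizon if year is None else year
    dist = _living_distribution(trace, year)
    living = dist.sum()
    if living <= 0:
        raise ValueError(f"no survivors at year {year}")
    shares = {band: float(dist[list(idx)].sum() / living) for band, idx in EDSS_BANDS.items()}
    shares["edss_7_9"] = shares["edss_7"] + shares["edss_8_9"]
    return shares


def mean_edss(trace: CohortTrace, year: int | None = None) -> float:
    """Occupancy-weighted mean integer EDSS among survivors."""
    year = trace.horizon if year is None else year
    dist = _living_distribution(trace, year)
    living = dist.sum()
    if living <= 0:
        raise ValueError(f"no survivors at year {year}")
    return float(dist @ np.arange(len(dist)) / living)


def years_in_band(trace: CohortTrace, band: tuple[int, ...]) -> float:
    """Undiscounted patient-years spent in a set of EDSS states.

    Counts the state at cycle boundaries 1..horizon, so a patient alive
    in the band for the whole horizon contributes exactly ``horizon``
    years.
    """
    idx = list(band)
    return float(
        sum(
            trace.states[t].edss_distribution()[idx].sum()
            for t in range(1, trace.horizon + 1)
        )
    )


def compute_yll(
    trace: CohortTrace, mortality: MortalityModel, discount_rate: float
) -> float:
    """Discounted years of life lost.

    Each death is weighted by the remaining general-population life
    expectancy at the integer age and sex at which it occurs, and
    discounted to present at the effects rate (deaths during cycle t are
    discounted by ``(1+r)^-t``).
    """
    start_age = math.floor(trace.start_age)
    total = 0.0
    for t in range(trace.horizon):
        df = (1.0 + discount_rate) ** (-t)
        for sex in (0, 1):
            d = trace.new_deaths_by_sex[t, sex]
            if d:
                total += d * mortality.remaining_life_expectancy(start_age + t, sex) * df
    return total


def compute_yld(trace: CohortTrace, weights: np.ndarray, discount_rate: float) -> float:
    """Discounted years lived with disability.

    Living state-years (start-of-cycle occupancy, cycles 0..horizon-1)
    weighted by the per-EDSS disability weights.
    """
    weights = np.asarray(weights, dtype=float)
    total = 0.0
    for t in range(trace.horizon):
        df = (1.0 + discount_rate) ** (-t)
        total += float(trace.states[t].edss_distribution() @ weights) * df
    return total


def total_relapses(trace: CohortTrace) -> float:
    """Undiscounted expected relapses per patient over the horizon."""
    return float(trace.expected_relapses_per_cycle.sum())


def productivity_and_informal_care(
    trace: CohortTrace, valuation: StateValuation, retirement_age: float
) -> dict[str, float]:
    """Horizon-year productivity shares and cumulative informal-care days.

    Employment, full-time and invalidity shares are occupancy-weighted
    per-EDSS fractions among survivors at the end of the horizon,
    defined only while the cohort is under retirement age (otherwise
    reported as 0 with ``working_age = 0``).  Informal-care days
    accumulate undiscounted over cycles 0..horizon-1.
    """
    final = trace.states[trace.horizon]
    dist = final.edss_distribution()
    living = dist.sum()
    if living <= 0:
        raise ValueError("no survivors at the end of the horizon")
    working_age = final.current_age < retirement_age
    if working_age:
        employed = float(dist @ valuation.employed_fraction / living)
        fulltime = float(dist @ valuation.fulltime_fraction / living)
        invalidity = float(dist @ valuation.invalidity_fraction / living)
    else:
        employed = fulltime = invalidity = 0.0
    days = float(
        sum(
            trace.states[t].edss_distribution() @ valuation.informal_care_days
            for t in range(trace.horizon)
        )
    )
    return {
        "employed_share": employed,
        "fulltime_share": fulltime,
        "invalidity_share": invalidity,
        "informal_care_days_total": days,
        "working_age": float(working_age),
    }


@dataclass
class OutcomeReport:
    """Table-shaped clinical, DALY, informal-care and productivity outcomes."""

    scenario_label: str
    band_shares: dict[str, float]
    mean_edss_by_year: np.ndarray  # (horizon + 1,)
    years_in_band: dict[str, float]
    total_relapses: float
    yld: float
    yll: float
    daly: float
    informal_care_days_total: float
    employed_share: float
    fulltime_share: float
    invalidity_share: float
    working_age: bool = True

    def metrics(self) -> dict[str, float]:
        """Flat metric dict (one row per metric, Table-1 style)."""
        out = {
            f"share_{band}": v for band, v in self.band_shares.items()
        }
        out.update(
            {f"years_in_{band}": v for band, v in self.years_in_band.items()}
        )
        out.update(
            {
                "mean_edss_final": float(self.mean_edss_by_year[-1]),
                "total_relapses": self.total_relapses,
                "yld": self.yld,
                "yll": self.yll,
                "daly": self.daly,
                "informal_care_days_total": self.informal_care_days_total,
                "employed_share": self.employed_share,
                "fulltime_share": self.fulltime_share,
                "invalidity_share": self.invalidity_share,
            }
        )
        return out


def build_outcome_report(trace: CohortTrace, params: ParameterSet) -> OutcomeReport:
    """Assemble the full outcome report for one scenario trace."""
    econ = params.economics
    yld = compute_yld(
        trace, params.valuation.disability_weight, econ.discount_rate_effects
    )
    yll = compute_yll(trace, params.mortality, econ.discount_rate_effects)
    prod = productivity_and_informal_care(
        trace, params.valuation, econ.retirement_age
    )
    return OutcomeReport(
        scenario_label=trace.scenario_label,
        band_shares=edss_band_shares(trace),
        mean_edss_by_year=np.array(
            [mean_edss(trace, t) for t in range(trace.horizon + 1)]
        ),
        years_in_band={
            band: years_in_band(trace, idx) for band, idx in EDSS_BANDS.items()
        },
        total_relapses=total_relapses(trace),
        yld=yld,
        yll=yll,
        daly=yld + yll,
        informal_care_days_total=prod["informal_care_days_total"],
        employed_share=prod["employed_share"],
        fulltime_share=prod["fulltime_share"],
        invalidity_share=prod["invalidity_share"],
        working_age=bool(prod["working_age"]),
    )
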