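"""Run orchestration and report writers.

`run_compare` executes the four built-in sequencing scenarios on one
ParameterSet and writes the full comparison bundle: per-scenario traces,
the outcome table (one row per metric, one column per scenario, plus
delta columns versus the immediate-OMB reference), the absolute and
percentage cost tables, the mean-EDSS-by-year and time-in-band series,
and a run manifest (parameter hash, seed, version).  `run_sensitivity`
writes the tornado table.  All numeric output is deterministic for a
given configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .costs import CostReport, compute_cost_report
from .engine import (
    SEX_LABELS,
    STATUS_LABELS,
    CohortTrace,
    run_scenario,
)
from .outcomes import OutcomeReport, build_outcome_report
from .parameters import (
    N_EDSS,
    ParameterSet,
    load_parameter_set,
    parameter_set_to_dict,
)
from .scenarios import ScenarioSpec, builtin_scenarios
from .sensitivity import DEFAULT_FACTORS, univariate_sensitivity
from .synthetic import SyntheticConfig, generate_parameter_set

__all__ = [
    "RunConfig",
    "resolve_parameters",
    "trace_to_frames",
    "outcome_table",
    "cost_tables",
    "run_compare",
    "run_sensitivity",
]

log = logging.getLogger("mscca")


@dataclass
class RunConfig:
    """Configuration of one comparison or sensitivity run.

    Exactly one of ``params_path`` (a parameter file) or ``seed``
    (synthetic inputs) must be given.
    """

    output_dir: str | Path
    params_path: str | Path | None = None
    seed: int | None = None
    comparator: str = "DMF"
    scenarios: list[ScenarioSpec] | None = None
    formats: tuple[str, ...] = ("csv", "json")
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.params_path is None) == (self.seed is None):
            raise ValueError("give exactly one of params_path or seed")
        unknown = set(self.formats) - {"csv", "json"}
        if unknown:
            raise ValueError(f"unknown report formats: {sorted(unknown)}")


def resolve_parameters(config: RunConfig) -> ParameterSet:
    if config.params_path is not None:
        return load_parameter_set(config.params_path)
    return generate_parameter_set(SyntheticConfig(seed=config.seed))


def _slug(label: str) -> str:
    return (
        label.lower()
        .replace(" ", "_")
        .replace("(", "")
        .replace(")", "")
        .replace("/", "-")
    )


def trace_to_frames(trace: CohortTrace) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy occupancy table and per-cycle summary for one trace."""
    rows = []
    for state in trace.states:
        for e in range(N_EDSS):
            for si, status in enumerate(STATUS_LABELS):
                for xi, sex in enumerate(SEX_LABELS):
                    rows.append(
                        {
                            "cycle": state.cycle_index,
                            "edss": e,
                            "treatment_status": status,
                            "sex": sex,
                            "mass": state.occupancy[e, si, xi],
                        }
                    )
    tidy = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "cycle": np.arange(trace.horizon),
            "active_treatment": trace.active_treatment_per_cycle,
            "new_deaths": trace.new_deaths_per_cycle,
            "dead_mass_end": [s.dead_mass for s in trace.states[1:]],
            "expected_relapses": trace.expected_relapses_per_cycle,
        }
    )
    return tidy, summary


def outcome_table(
    reports: list[OutcomeReport], reference_label: str
) -> pd.DataFrame:
    """Metric x scenario table with delta columns versus the reference."""
    cols = {r.scenario_label: pd.Series(r.metrics()) for r in reports}
    df = pd.DataFrame(cols)
    ref = df[reference_label]
    for r in reports:
        if r.scenario_label != reference_label:
            df[f"delta[{r.scenario_label}]"] = df[r.scenario_label] - ref
    df.index.name = "metric"
    return df


def cost_tables(
    reports: list[CostReport], reference_label: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Absolute cost table (with percent deltas vs reference) and share table."""
    absolute = pd.DataFrame(
        {r.scenario_label: pd.Series(r.metrics()) for r in reports}
    )
    ref = absolute[reference_label]
    for r in reports:
        if r.scenario_label != reference_label:
            with np.errstate(divide="ignore", invalid="ignore"):
                absolute[f"delta_pct[{r.scenario_label}]"] = (
                    100.0 * (absolute[r.scenario_label] - ref) / ref
                ).replace([np.inf, -np.inf], np.nan)
    absolute.index.name = "metric"
    shares = pd.DataFrame({r.scenario_label: pd.Series(r.shares) for r in reports})
    shares.index.name = "share"
    return absolute, shares


def _write(df: pd.DataFrame, stem: Path, formats: tuple[str, ...]) -> None:
    if "csv" in formats:
        df.to_csv(stem.with_suffix(".csv"))
    if "json" in formats:
        df.to_json(stem.with_suffix(".json"), orient="columns", double_precision=12)


def _manifest(config: RunConfig, params: ParameterSet) -> dict:
    blob = json.dumps(parameter_set_to_dict(params), sort_keys=True).encode()
    return {
        "parameter_hash": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "params_path": str(config.params_path) if config.params_path else None,
        "comparator": config.comparator,
        "mscca_version": __version__,
    }


def run_compare(config: RunConfig) -> dict[str, Path]:
    """Run the four-scenario comparison and write the report bundle.

    Returns a name -> path map of everything written.  The reference
    scenario for all delta columns is the immediate-OMB base scenario.
    """
    logging.basicConfig(level=config.log_level)
    params = resolve_parameters(config)
    horizon = params.economics.horizon_years
    specs = config.scenarios or builtin_scenarios(config.comparator, horizon)
    reference_label = specs[0].label

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    traces, outcome_reports, cost_reports = [], [], []
    for spec in specs:
        log.info("running scenario %s", spec.label)
        trace = run_scenario(params, spec)
        traces.append(trace)
        outcome_reports.append(build_outcome_report(trace, params))
        cost_reports.append(compute_cost_report(trace, params, spec))
        tidy, summary = trace_to_frames(trace)
        slug = _slug(spec.label)
        for name, df in (("trace", tidy), ("summary", summary)):
            p = outdir / f"{name}_{slug}.csv"
            df.to_csv(p, index=False)
            written[f"{name}_{slug}"] = p

    _write(outcome_table(outcome_reports, reference_label), outdir / "outcomes", config.formats)
    absolute, shares = cost_tables(cost_reports, reference_label)
    _write(absolute, outdir / "costs_absolute", config.formats)
    _write(shares, outdir / "costs_shares", config.formats)

    mean_edss = pd.DataFrame(
        {r.scenario_label: r.mean_edss_by_year for r in outcome_reports}
    )
    mean_edss.index.name = "year"
    _write(mean_edss, outdir / "mean_edss_by_year", config.formats)

    band_years = pd.DataFrame(
        {r.scenario_label: pd.Series(r.years_in_band) for r in outcome_reports}
    )
    band_years.index.name = "band"
    _write(band_years, outdir / "years_in_band", config.formats)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(_manifest(config, params), indent=2))
    written["manifest"] = manifest_path
    for stem in ("outcomes", "costs_absolute", "costs_shares", "mean_edss_by_year", "years_in_band"):
        for fmt in config.formats:
            written[f"{stem}.{fmt}"] = outdir / f"{stem}.{fmt}"
    return written


def run_sensitivity(
    config: RunConfig, factors: list[str] | None = None
) -> dict[str, Path]:
    """Run the one-way sensitivity analysis and write the tornado table.

    ``factors`` selects a subset of the default factor names; an empty
    list yields an empty table (and succeeds).
    """
    logging.basicConfig(level=config.log_level)
    params = resolve_parameters(config)
    horizon = params.economics.horizon_years
    specs = config.scenarios or builtin_scenarios(config.comparator, horizon)
    # reference = immediate OMB, comparator = no-switch standard therapy
    pair = (specs[0], specs[-1])

    if factors is None:
        selected = DEFAULT_FACTORS
    else:
        unknown = set(factors) - set(DEFAULT_FACTORS)
        if unknown:
            raise ValueError(f"unknown sensitivity factors: {sorted(unknown)}")
        selected = {k: DEFAULT_FACTORS[k] for k in factors}

    results = univariate_sensitivity(params, pair, factors=selected)
    for r in results:
        for direction in ("low", "high"):
            log.info(
                "sensitivity rerun factor=%s direction=%s value=%s",
                r.factor,
                direction,
                getattr(r, f"{direction}_value"),
            )

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {
                "factor": r.factor,
                "low": r.low_value,
                "base": r.base_value,
                "high": r.high_value,
                "range": r.range,
                "notes": "; ".join(r.notes),
            }
            for r in results
        ],
        columns=["factor", "low", "base", "high", "range", "notes"],
    )
    written = {}
    p = outdir / "tornado.csv"
    df.to_csv(p, index=False)
    written["tornado.csv"] = p
    if "json" in config.formats:
        p = outdir / "tornado.json"
        df.to_json(p, orient="records", double_precision=12)
        written["tornado.json"] = p
    return written
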