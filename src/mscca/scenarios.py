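"""Treatment-sequencing scenarios.

A scenario is an ordered list of (treatment, duration) segments covering
a fixed horizon.  The four built-in scenarios compare immediate
initiation of the high-efficacy therapy (OMB) against switching from a
standard therapy (DMF or GA) after one year, after five years, or never:

======================  ==========================================
label                   sequence
======================  ==========================================
Base-Scenario (10/0)    OMB for the whole horizon
Scenario A (1/9)        comparator 1 year, then OMB
Scenario B (5/5)        comparator 5 years, then OMB
Base-Scenario (0/10)    comparator for the whole horizon
======================  ==========================================

Switches happen exactly at cycle boundaries (end of year 1 / year 5).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ScenarioSpec",
    "builtin_scenarios",
    "active_treatment",
    "treatment_start_cycle",
    "DEFAULT_HORIZON",
]

DEFAULT_HORIZON = 10

OMB = "OMB"
COMPARATORS = ("DMF", "GA")


@dataclass(frozen=True)
class ScenarioSpec:
    """An ordered treatment sequence over a fixed horizon (years)."""

    label: str
    segments: tuple[tuple[str, int], ...]
    horizon: int

    def __post_init__(self):
        object.__setattr__(
            self, "segments", tuple((str(n), int(d)) for n, d in self.segments)
        )
        if any(d <= 0 for _, d in self.segments):
            raise ValueError(f"{self.label}: segment durations must be positive")
        total = sum(d for _, d in self.segments)
        if total != self.horizon:
            raise ValueError(
                f"{self.label}: segment durations sum to {total}, "
                f"expected horizon {self.horizon}"
            )

    def treatment_names(self) -> set[str]:
        return {n for n, _ in self.segments}

    def boundaries(self) -> list[tuple[str, int, int]]:
        """List of (treatment, start_cycle, end_cycle) half-open segments."""
        out, start = [], 0
        for name, dur in self.segments:
            out.append((name, start, start + dur))
            start += dur
        return out


def builtin_scenarios(
    comparator: str, horizon: int = DEFAULT_HORIZON
) -> list[ScenarioSpec]:
    """The four standard sequencing scenarios versus one comparator.

    With the default 10-year horizon the switch scenarios place the
    switch after 1 year (early) and after 5 years (late); for other
    horizons the same early/late years are kept where they fit.
    """
    if comparator not in COMPARATORS:
        raise ValueError(
            f"unknown comparator {comparator!r}; expected one of {COMPARATORS}"
        )
    early, late = 1, 5
    if horizon <= late:
        raise ValueError(f"horizon must exceed the late switch year {late}")
    return [
        ScenarioSpec(
            label=f"Base-Scenario ({horizon}/0)",
            segments=((OMB, horizon),),
            horizon=horizon,
        ),
        ScenarioSpec(
            label=f"Scenario A ({early}/{horizon - early})",
            segments=((comparator, early), (OMB, horizon - early)),
            horizon=horizon,
        ),
        ScenarioSpec(
            label=f"Scenario B ({late}/{horizon - late})",
            segments=((comparator, late), (OMB, horizon - late)),
            horizon=horizon,
        ),
        ScenarioSpec(
            label=f"Base-Scenario (0/{horizon})",
            segments=((comparator, horizon),),
            horizon=horizon,
        ),
    ]


def _segment_at(spec: ScenarioSpec, cycle: int) -> tuple[str, int, int]:
    if not (0 <= cycle < spec.horizon):
        raise ValueError(
            f"cycle {cycle} outside scenario horizon [0, {spec.horizon})"
        )
    for name, start, end in spec.boundaries():
        if start <= cycle < end:
            return name, start, end
    raise AssertionError("unreachable: segments cover the horizon")


def active_treatment(spec: ScenarioSpec, cycle: int) -> str:
    """Treatment in force during cycle ``cycle`` (half-open segments)."""
    return _segment_at(spec, cycle)[0]


def treatment_start_cycle(spec: ScenarioSpec, cycle: int) -> int:
    """First cycle of the segment containing ``cycle``.

    Used to price year-1 versus subsequent drug years relative to the
    initiation of the currently active therapy within the scenario.
    """
    return _segment_at(spec, cycle)[1]
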