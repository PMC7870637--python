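"""Health-economic cost model for the diagnostic pathway.

Patients are binned into four CT-by-surgery utilisation groups with
fixed per-case tariffs (EUR): surgery without CT (1317), surgery with CT
(1434), CT without surgery (675), and neither (558 in hospital, 250 in a
purely ambulatory work-up).  A scenario couples group proportions with
those tariffs and a case volume (default 100,000 suspected-appendicitis
presentations) to give a total cost; differencing two scenarios gives
the projected saving.

The published scenario proportions are bundled verbatim
(:data:`PAPER_SCENARIOS`).  The published scenario *totals* cannot be
re-derived from those proportions and tariffs, so this module's
arithmetic — not the printed totals — is the contract; recomputed totals
are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .pathway import CareSetting, CostGroup, PathwayTrace, classify_cost_group

__all__ = [
    "DEFAULT_UNIT_COSTS",
    "PAPER_SCENARIOS",
    "CostScenario",
    "total_cost",
    "scenario_saving",
    "proportions_from_traces",
]

#: Per-case tariffs in EUR by utilisation group.
DEFAULT_UNIT_COSTS: dict[str, float] = {
    "G1": 1317.0,
    "G2": 1434.0,
    "G3": 675.0,
    "G4_HOSPITAL": 558.0,
    "G4_AMBULATORY": 250.0,
}

_GROUP_KEYS = tuple(DEFAULT_UNIT_COSTS)

_PROPORTION_SUM_TOL = 0.01  # published proportion sets do not all sum to 1


@dataclass(frozen=True)
class CostScenario:
    """Group proportions x tariffs x case volume."""

    name: str
    proportions: dict[str, float]
    unit_costs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_UNIT_COSTS))
    n_cases: int = 100_000

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError(f"n_cases must be >= 0, got {self.n_cases}")
        for key, p in self.proportions.items():
            if key not in _GROUP_KEYS:
                raise ValueError(f"unknown cost group {key!r}; expected one of {_GROUP_KEYS}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion for {key} must lie in [0, 1], got {p}")
        if sum(self.proportions.values()) > 1.0 + _PROPORTION_SUM_TOL:
            raise ValueError(
                f"scenario {self.name!r}: proportions sum to "
                f"{sum(self.proportions.values()):.4f} > 1"
            )
        for key, c in self.unit_costs.items():
            if c < 0:
                raise ValueError(f"unit cost for {key} must be >= 0, got {c}")


def total_cost(scenario: CostScenario) -> float:
    """Total cost in EUR: sum over groups of proportion x tariff x volume."""
    return sum(
        p * scenario.unit_costs[key] * scenario.n_cases
        for key, p in scenario.proportions.items()
    )


def scenario_saving(a: CostScenario, b: CostScenario) -> float:
    """Signed saving ``total_cost(a) - total_cost(b)`` (EUR).

    Positive when scenario ``b`` is cheaper.  Scenarios must share the
    case volume, otherwise the difference is meaningless.
    """
    if a.n_cases != b.n_cases:
        raise ValueError(
            f"case volumes differ: {a.name!r} has {a.n_cases}, {b.name!r} has {b.n_cases}"
        )
    return total_cost(a) - total_cost(b)


def proportions_from_traces(
    traces: list[PathwayTrace], denominator_mode: str = "ALL_PATIENTS"
) -> dict[str, float]:
    """Empirical cost-group proportions of a cohort run.

    ``"ALL_PATIENTS"`` divides every group (with the no-CT/no-surgery
    group split into hospital and ambulatory settings) by the cohort
    size.  ``"CT_OR_SURGERY_ONLY"`` restricts to patients who had CT or
    surgery, the published three-group convention.
    """
    if not traces:
        raise ValueError("no traces: empty denominator")
    counts = {key: 0 for key in _GROUP_KEYS}
    for t in traces:
        group, setting = classify_cost_group(t)
        if group is CostGroup.G1_SURGERY_NO_CT:
            counts["G1"] += 1
        elif group is CostGroup.G2_SURGERY_CT:
            counts["G2"] += 1
        elif group is CostGroup.G3_CT_NO_SURGERY:
            counts["G3"] += 1
        elif setting is CareSetting.AMBULATORY:
            counts["G4_AMBULATORY"] += 1
        else:
            counts["G4_HOSPITAL"] += 1

    if denominator_mode == "ALL_PATIENTS":
        denom = len(traces)
        keys = _GROUP_KEYS
    elif denominator_mode == "CT_OR_SURGERY_ONLY":
        keys = ("G1", "G2", "G3")
        denom = sum(counts[k] for k in keys)
        if denom == 0:
            raise ValueError("no CT or surgery patients: empty denominator")
    else:
        raise ValueError(f"unknown denominator mode: {denominator_mode!r}")
    return {k: counts[k] / denom for k in keys}


#: Published scenario proportion sets, verbatim.  Each pair in the source
#: reads "pre-pathway / pathway"; the three-group sets refer only to
#: patients with CT or surgery, the four-group sets to all patients.
PAPER_SCENARIOS: dict[str, CostScenario] = {
    "three_group_pre_pathway": CostScenario(
        name="three_group_pre_pathway",
        proportions={"G1": 0.52, "G2": 0.17, "G3": 0.19},
    ),
    "three_group_pathway": CostScenario(
        name="three_group_pathway",
        proportions={"G1": 0.59, "G2": 0.19, "G3": 0.22},
    ),
    "four_group_pre_pathway": CostScenario(
        name="four_group_pre_pathway",
        proportions={
            "G1": 0.34,
            "G2": 0.125,
            "G3": 0.059,
            "G4_AMBULATORY": 0.10,
            "G4_HOSPITAL": 0.376,
        },
    ),
    "four_group_pathway": CostScenario(
        name="four_group_pathway",
        proportions={
            "G1": 0.284,
            "G2": 0.092,
            "G3": 0.103,
            "G4_AMBULATORY": 0.10,
            "G4_HOSPITAL": 0.419,
        },
    ),
}
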