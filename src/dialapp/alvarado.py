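"""Alvarado score computation and risk stratification.

The Alvarado score is a 10-point clinical prediction rule for acute
appendicitis built from eight weighted binary items: three symptoms
(pain migration to the right lower quadrant, anorexia, nausea/vomiting),
three clinical signs (right-lower-quadrant tenderness, rebound pain,
temperature > 37.5 degC) and two laboratory findings (leukocytosis,
neutrophil left shift > 75%).  Tenderness and leukocytosis carry weight 2,
every other item weight 1.

The diagnostic pathway stratifies the score into three management bands:
low scores are discharged when ultrasound is negative, intermediate
scores are admitted for observation and re-evaluation, and high scores
are advised to undergo appendectomy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields

__all__ = [
    "ITEM_WEIGHTS",
    "AlvaradoComponents",
    "RiskStratum",
    "RiskThresholds",
    "compute_score",
    "risk_stratum",
]

#: Item weights in the canonical order of the score sheet.
ITEM_WEIGHTS: dict[str, int] = {
    "migration_rlq": 1,
    "anorexia": 1,
    "nausea_vomiting": 1,
    "tenderness_rlq": 2,
    "rebound_pain": 1,
    "temperature_gt_37_5": 1,
    "leukocytosis": 2,
    "neutrophils_gt_75": 1,
}


@dataclass(frozen=True)
class AlvaradoComponents:
    """The eight binary items of the Alvarado score.

    Every item must be resolved to a strict boolean before scoring;
    scoring on partial data is a protocol violation and raises.
    """

    migration_rlq: bool
    anorexia: bool
    nausea_vomiting: bool
    tenderness_rlq: bool
    rebound_pain: bool
    temperature_gt_37_5: bool
    leukocytosis: bool
    neutrophils_gt_75: bool

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not isinstance(value, bool):
                raise TypeError(
                    f"Alvarado item {f.name!r} must be a resolved boolean, "
                    f"got {value!r}"
                )

    def as_dict(self) -> dict[str, bool]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class RiskStratum(enum.Enum):
    """Management band implied by the score."""

    LOW = "LOW"
    INTERMEDIATE = "INTERMEDIATE"
    HIGH = "HIGH"


@dataclass(frozen=True)
class RiskThresholds:
    """Score cut points delimiting the three management bands.

    Defaults implement the pathway's triage rule: score <= 4 with a
    negative ultrasound is discharged, 5-8 is observed, > 8 goes to
    surgery.  The bands must tile [0, 10] without gap or overlap.
    """

    discharge_max: int = 4
    observe_min: int = 5
    observe_max: int = 8
    surgery_min: int = 9

    def __post_init__(self) -> None:
        vals = (self.discharge_max, self.observe_min, self.observe_max, self.surgery_min)
        if not all(isinstance(v, int) for v in vals):
            raise TypeError("thresholds must be integers")
        if not all(0 <= v <= 10 for v in vals):
            raise ValueError(f"thresholds must lie in [0, 10], got {vals}")
        if self.discharge_max + 1 != self.observe_min:
            raise ValueError(
                "observation band must start right above the discharge band "
                f"(discharge_max={self.discharge_max}, observe_min={self.observe_min})"
            )
        if self.observe_max + 1 != self.surgery_min:
            raise ValueError(
                "surgery band must start right above the observation band "
                f"(observe_max={self.observe_max}, surgery_min={self.surgery_min})"
            )


def compute_score(components: AlvaradoComponents) -> int:
    """Return the Alvarado score, the weighted sum of present items.

    Parameters
    ----------
    components
        Fully resolved item booleans.

    Returns
    -------
    int
        Score in [0, 10].
    """
    if not isinstance(components, AlvaradoComponents):
        raise TypeError("components must be an AlvaradoComponents instance")
    return sum(
        weight for item, weight in ITEM_WEIGHTS.items() if getattr(components, item)
    )


def risk_stratum(score: int, thresholds: RiskThresholds | None = None) -> RiskStratum:
    """Map an integer score to its management band.

    LOW iff ``score <= discharge_max``, INTERMEDIATE iff
    ``observe_min <= score <= observe_max``, HIGH iff
    ``score >= surgery_min``.
    """
    if thresholds is None:
        thresholds = RiskThresholds()
    if not isinstance(score, int) or isinstance(score, bool):
        raise TypeError(f"score must be an integer, got {score!r}")
    if not 0 <= score <= 10:
        raise ValueError(f"score must lie in [0, 10], got {score}")
    if score <= thresholds.discharge_max:
        return RiskStratum.LOW
    if score <= thresholds.observe_max:
        return RiskStratum.INTERMEDIATE
    return RiskStratum.HIGH
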