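"""Decision engine for the risk-stratified appendicitis diagnostic pathway.

The pathway triages adult patients presenting with suspected acute
appendicitis using the Alvarado score, routine surgeon-performed
ultrasound, a gynecological consultation for women of childbearing age,
in-hospital observation with clinical re-evaluation for the equivocal
middle band, and selective CT (MRI when pregnant) only for patients whose
complaints persist under observation.  Exits are surgery, discharge, or
alternative-diagnosis care.

Each patient carries *latent* test results: the result every test would
give if ordered.  The engine reads a latent result only when the pathway
actually orders the test, which is what makes selective imaging rates
meaningful on simulated cohorts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .alvarado import AlvaradoComponents, RiskThresholds, compute_score

__all__ = [
    "TestResult",
    "Disposition",
    "SurgeryTrigger",
    "CostGroup",
    "CareSetting",
    "PatientRecord",
    "PathwayConfig",
    "TraceEvent",
    "PathwayTrace",
    "CohortFlowSummary",
    "evaluate_patient",
    "run_cohort",
    "classify_cost_group",
]


class TestResult(enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    ALTERNATIVE_DX = "ALTERNATIVE_DX"


class Disposition(enum.Enum):
    SURGERY = "SURGERY"
    DISCHARGE = "DISCHARGE"
    ALTERNATIVE_CARE = "ALTERNATIVE_CARE"


class SurgeryTrigger(enum.Enum):
    CLINICAL = "CLINICAL"
    ULTRASOUND = "ULTRASOUND"
    CT = "CT"
    NONE = "NONE"


class CostGroup(enum.Enum):
    """CT-by-surgery utilisation category used by the cost model."""

    G1_SURGERY_NO_CT = "G1_SURGERY_NO_CT"
    G2_SURGERY_CT = "G2_SURGERY_CT"
    G3_CT_NO_SURGERY = "G3_CT_NO_SURGERY"
    G4_NO_CT_NO_SURGERY = "G4_NO_CT_NO_SURGERY"


class CareSetting(enum.Enum):
    HOSPITAL = "HOSPITAL"
    AMBULATORY = "AMBULATORY"


class UnresolvedLatentError(RuntimeError):
    """A test was ordered but its latent result is missing."""


@dataclass
class PatientRecord:
    """One patient: latent disease truth plus observable attributes.

    ``true_appendicitis`` and ``perforated`` are the histology-level
    ground truth; test latents (``us_latent``, ``ct_latent``,
    ``gyn_alternative_dx``) and observation latents are realised up front
    but only read when the pathway orders the corresponding step.
    """

    patient_id: str
    age_years: float
    sex: str  # "F" or "M"
    pregnant: bool
    childbearing_age: bool
    true_appendicitis: bool
    perforated: bool
    peritonitis: bool
    alvarado: AlvaradoComponents
    us_latent: TestResult | None = None
    ct_latent: TestResult | None = None
    gyn_alternative_dx: bool | None = None
    observation_resolves: bool = False
    observation_clinical_aa: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.age_years < 18:
            raise ValueError(
                f"patient {self.patient_id}: age {self.age_years} < 18 "
                "(adults only)"
            )
        if self.perforated and not self.true_appendicitis:
            raise ValueError(
                f"patient {self.patient_id}: perforation without appendicitis"
            )
        if self.pregnant and self.sex != "F":
            raise ValueError(f"patient {self.patient_id}: pregnant male record")
        if self.gyn_alternative_dx is not None and not (
            self.sex == "F" and self.childbearing_age
        ):
            raise ValueError(
                f"patient {self.patient_id}: gynecological consult result on a "
                "patient who is not a female of childbearing age"
            )


@dataclass(frozen=True)
class PathwayConfig:
    """Tunable pathway parameters.

    ``max_observation_hours`` is informational (the protocol re-evaluates
    within 24 h); it does not alter decisions.
    """

    thresholds: RiskThresholds = field(default_factory=RiskThresholds)
    require_gyn_consult_for_childbearing_females: bool = True
    max_observation_hours: float = 24.0


@dataclass(frozen=True)
class TraceEvent:
    step: str
    test: str | None = None
    result: str | None = None


@dataclass
class PathwayTrace:
    """Ordered decision log for one patient, ending in one disposition."""

    patient_id: str
    events: list[TraceEvent]
    tests_performed: set[str]
    disposition: Disposition
    surgery_trigger: SurgeryTrigger
    observed: bool
    score: int
    imaging_label: str | None = None  # "CT" or "MRI" when cross-sectional imaging used


def _read(record: PatientRecord, attr: str):
    value = getattr(record, attr)
    if value is None:
        raise UnresolvedLatentError(
            f"patient {record.patient_id}: latent result {attr!r} was ordered "
            "but is unresolved"
        )
    return value


def evaluate_patient(record: PatientRecord, config: PathwayConfig | None = None) -> PathwayTrace:
    """Run one patient through the pathway and return the decision trace.

    Decision order: gynecological consult (childbearing-age females) ->
    ultrasound alternative-diagnosis exit -> surgery rule (peritonitis,
    score above the surgery threshold, or positive ultrasound) ->
    low-score/negative-ultrasound discharge -> observation, where
    clinically evident appendicitis goes to surgery, resolution to
    discharge, and persistent complaints to CT (MRI when pregnant) whose
    result decides surgery, discharge, or alternative care.

    The function is pure: identical inputs give identical traces.
    """
    if config is None:
        config = PathwayConfig()
    events: list[TraceEvent] = []
    tests: set[str] = set()

    score = compute_score(record.alvarado)
    events.append(TraceEvent("alvarado", result=str(score)))

    def done(disposition, trigger, observed, imaging_label=None):
        return PathwayTrace(
            patient_id=record.patient_id,
            events=events,
            tests_performed=tests,
            disposition=disposition,
            surgery_trigger=trigger,
            observed=observed,
            score=score,
            imaging_label=imaging_label,
        )

    # 1. gynecological consultation for females of childbearing age
    if (
        record.sex == "F"
        and record.childbearing_age
        and config.require_gyn_consult_for_childbearing_females
    ):
        tests.add("GYN")
        gyn_alt = _read(record, "gyn_alternative_dx")
        events.append(TraceEvent("gyn_consult", test="GYN", result="ALTERNATIVE_DX" if gyn_alt else "NO_ALTERNATIVE"))
        if gyn_alt:
            return done(Disposition.ALTERNATIVE_CARE, SurgeryTrigger.NONE, observed=False)

    # 2. routine ultrasound; an alternative diagnosis exits the pathway
    tests.add("US")
    us = _read(record, "us_latent")
    events.append(TraceEvent("ultrasound", test="US", result=us.value))
    if us is TestResult.ALTERNATIVE_DX:
        return done(Disposition.ALTERNATIVE_CARE, SurgeryTrigger.NONE, observed=False)

    # 3. surgery rule: peritonitis, high score, or positive ultrasound
    if record.peritonitis or score >= config.thresholds.surgery_min:
        events.append(TraceEvent("surgery_rule", result="CLINICAL"))
        return done(Disposition.SURGERY, SurgeryTrigger.CLINICAL, observed=False)
    if us is TestResult.POSITIVE:
        events.append(TraceEvent("surgery_rule", result="ULTRASOUND"))
        return done(Disposition.SURGERY, SurgeryTrigger.ULTRASOUND, observed=False)

    # 4. low score with negative ultrasound: discharge without admission
    if score <= config.thresholds.discharge_max:
        events.append(TraceEvent("discharge_rule", result="LOW_SCORE_NEGATIVE_US"))
        return done(Disposition.DISCHARGE, SurgeryTrigger.NONE, observed=False)

    # 5. equivocal: admit for observation and clinical re-evaluation
    events.append(TraceEvent("observation"))
    if record.observation_clinical_aa:
        events.append(TraceEvent("reevaluation", result="CLINICAL_AA"))
        return done(Disposition.SURGERY, SurgeryTrigger.CLINICAL, observed=True)
    if record.observation_resolves:
        events.append(TraceEvent("reevaluation", result="RESOLVED"))
        return done(Disposition.DISCHARGE, SurgeryTrigger.NONE, observed=True)

    # persistent complaints: cross-sectional imaging (MRI substitutes for
    # CT in pregnancy with identical operating characteristics)
    label = "MRI" if record.pregnant else "CT"
    tests.add("CT_or_MRI")
    ct = _read(record, "ct_latent")
    events.append(TraceEvent("imaging", test=label, result=ct.value))
    if ct is TestResult.POSITIVE:
        return done(Disposition.SURGERY, SurgeryTrigger.CT, observed=True, imaging_label=label)
    if ct is TestResult.NEGATIVE:
        return done(Disposition.DISCHARGE, SurgeryTrigger.NONE, observed=True, imaging_label=label)
    return done(Disposition.ALTERNATIVE_CARE, SurgeryTrigger.NONE, observed=True, imaging_label=label)


@dataclass
class CohortFlowSummary:
    """Branch counts over a cohort run; additive and conserving."""

    n: int
    operated: int
    operated_clinical: int
    operated_ultrasound: int
    operated_ct: int
    observed: int
    recovered_in_observation: int
    ct_performed: int
    ct_positive: int
    ct_negative: int
    ct_alternative: int
    discharged: int
    alternative_dx: int

    def check(self) -> None:
        if self.operated + self.discharged + self.alternative_dx != self.n:
            raise AssertionError("flow not conserved: exits do not sum to n")
        if self.operated_clinical + self.operated_ultrasound + self.operated_ct != self.operated:
            raise AssertionError("surgery triggers do not sum to operated")
        if self.ct_positive + self.ct_negative + self.ct_alternative != self.ct_performed:
            raise AssertionError("CT outcomes do not sum to CT performed")


def run_cohort(
    records: list[PatientRecord], config: PathwayConfig | None = None
) -> tuple[list[PathwayTrace], CohortFlowSummary]:
    """Evaluate every patient and tally the branch counts."""
    if not records:
        raise ValueError("cohort must be non-empty")
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids: {dupes}")
    if config is None:
        config = PathwayConfig()

    traces = [evaluate_patient(r, config) for r in records]

    def count(pred):
        return sum(1 for t in traces if pred(t))

    summary = CohortFlowSummary(
        n=len(traces),
        operated=count(lambda t: t.disposition is Disposition.SURGERY),
        operated_clinical=count(lambda t: t.surgery_trigger is SurgeryTrigger.CLINICAL),
        operated_ultrasound=count(lambda t: t.surgery_trigger is SurgeryTrigger.ULTRASOUND),
        operated_ct=count(lambda t: t.surgery_trigger is SurgeryTrigger.CT),
        observed=count(lambda t: t.observed),
        recovered_in_observation=count(
            lambda t: t.observed
            and t.disposition is Disposition.DISCHARGE
            and "CT_or_MRI" not in t.tests_performed
        ),
        ct_performed=count(lambda t: "CT_or_MRI" in t.tests_performed),
        ct_positive=count(lambda t: t.surgery_trigger is SurgeryTrigger.CT),
        ct_negative=count(
            lambda t: "CT_or_MRI" in t.tests_performed
            and t.disposition is Disposition.DISCHARGE
        ),
        ct_alternative=count(
            lambda t: "CT_or_MRI" in t.tests_performed
            and t.disposition is Disposition.ALTERNATIVE_CARE
        ),
        discharged=count(lambda t: t.disposition is Disposition.DISCHARGE),
        alternative_dx=count(lambda t: t.disposition is Disposition.ALTERNATIVE_CARE),
    )
    summary.check()
    return traces, summary


def classify_cost_group(
    trace: PathwayTrace, ambulatory_if_never_admitted: bool = True
) -> tuple[CostGroup, CareSetting]:
    """Assign a trace to its CT-by-surgery cost group and care setting.

    The ambulatory tariff applies only to patients who used no CT, had no
    surgery, and were never admitted for observation.
    """
    ct = "CT_or_MRI" in trace.tests_performed
    surgery = trace.disposition is Disposition.SURGERY
    if surgery and not ct:
        group = CostGroup.G1_SURGERY_NO_CT
    elif surgery and ct:
        group = CostGroup.G2_SURGERY_CT
    elif ct:
        group = CostGroup.G3_CT_NO_SURGERY
    else:
        group = CostGroup.G4_NO_CT_NO_SURGERY
    setting = CareSetting.HOSPITAL
    if (
        group is CostGroup.G4_NO_CT_NO_SURGERY
        and ambulatory_if_never_admitted
        and not trace.observed
    ):
        setting = CareSetting.AMBULATORY
    return group, setting
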