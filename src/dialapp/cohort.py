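"""Synthetic patient cohorts for the appendicitis diagnostic pathway.

Two sources of cohorts are provided:

``generate_cohort``
    Stochastic cohorts drawn from the study's assumed statistical
    structure: appendicitis prevalence near 65/183 with a marked
    male excess, surgeon-performed ultrasound with sensitivity 0.582 and
    specificity 0.973, perfect CT, itemwise Bernoulli Alvarado components
    calibrated so the median score is 7 among cases and 4 among
    non-cases, and latent observation-phase outcomes.

``build_fixture_cohort``
    A deterministic 183-patient cohort constructed so the pathway engine
    replays the study's printed patient flow exactly: 69 appendectomies
    (27 clinical-trigger, 25 ultrasound-trigger, 17 CT-trigger), 4 of
    them negative (1 female of 23 female surgeries, 3 male of 46), 17
    perforations among the 65 true cases, 36 CT scans (17 positive, 10
    negative discharges, 9 alternative diagnoses), 87 discharges and 27
    alternative-diagnosis exits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .alvarado import ITEM_WEIGHTS, AlvaradoComponents
from .pathway import PatientRecord, TestResult

__all__ = [
    "CohortParams",
    "FixtureSpec",
    "generate_cohort",
    "build_fixture_cohort",
    "components_for_score",
    "write_cohort",
    "read_cohort",
]

_ITEMS = list(ITEM_WEIGHTS)

#: Itemwise Bernoulli probabilities for the eight Alvarado components,
#: calibrated by simulation (scripts/calibrate_components.py) so that the
#: median total score is 7 among patients with appendicitis and 4 among
#: patients without, matching the cohort the generator emulates.
COMPONENT_PROBS_DISEASED: tuple[float, ...] = (0.60, 0.60, 0.65, 0.95, 0.60, 0.50, 0.80, 0.60)
COMPONENT_PROBS_HEALTHY: tuple[float, ...] = (0.25, 0.30, 0.35, 0.70, 0.25, 0.20, 0.35, 0.30)


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass(frozen=True)
class CohortParams:
    """Sampling parameters of the stochastic cohort generator.

    Defaults reproduce, in expectation, the marginal structure of the
    validation cohort: prevalence 65/183 split as 22/91 among women and
    43/92 among men, ultrasound sensitivity/specificity 58.2%/97.3%, and
    perfect CT.  ``prevalence`` is used only when the sex-conditional
    disease rates are ``None``.
    """

    n_patients: int = 183
    prevalence: float = 65 / 183
    perforation_given_disease: float = 17 / 65
    p_female: float = 91 / 183
    disease_given_female: float | None = 22 / 91
    disease_given_male: float | None = 43 / 92
    us_sens: float = 0.582
    us_spec: float = 0.973
    ct_sens: float = 1.0
    ct_spec: float = 1.0
    p_us_alternative_dx_given_healthy: float = 0.08
    p_ct_alternative_dx_given_healthy: float = 9 / 19
    p_gyn_alternative_dx: float = 0.10
    p_peritonitis_given_disease: float = 0.15
    component_probs_diseased: tuple[float, ...] = COMPONENT_PROBS_DISEASED
    component_probs_healthy: tuple[float, ...] = COMPONENT_PROBS_HEALTHY
    p_obs_resolution_given_healthy: float = 21 / 40
    p_obs_clinical_aa_given_disease: float = 0.25
    p_pregnant_given_childbearing: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        for name in (
            "prevalence",
            "perforation_given_disease",
            "p_female",
            "us_sens",
            "us_spec",
            "ct_sens",
            "ct_spec",
            "p_us_alternative_dx_given_healthy",
            "p_ct_alternative_dx_given_healthy",
            "p_gyn_alternative_dx",
            "p_peritonitis_given_disease",
            "p_obs_resolution_given_healthy",
            "p_obs_clinical_aa_given_disease",
            "p_pregnant_given_childbearing",
        ):
            _check_prob(name, getattr(self, name))
        for name in ("disease_given_female", "disease_given_male"):
            v = getattr(self, name)
            if v is not None:
                _check_prob(name, v)
        for name in ("component_probs_diseased", "component_probs_healthy"):
            probs = getattr(self, name)
            if len(probs) != 8:
                raise ValueError(f"{name} must have 8 entries, got {len(probs)}")
            for i, p in enumerate(probs):
                _check_prob(f"{name}[{i}]", p)


def generate_cohort(params: CohortParams) -> list[PatientRecord]:
    """Draw a cohort of independent synthetic patients.

    Every latent test result is realised for every patient (the pathway
    reads them lazily).  Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    female = rng.random(n) < params.p_female
    if params.disease_given_female is not None and params.disease_given_male is not None:
        p_disease = np.where(female, params.disease_given_female, params.disease_given_male)
    else:
        p_disease = np.full(n, params.prevalence)
    diseased = rng.random(n) < p_disease
    perforated = diseased & (rng.random(n) < params.perforation_given_disease)
    peritonitis = diseased & (rng.random(n) < params.p_peritonitis_given_disease)

    # ages are realism-only (the engine never reads them); gamma families
    # give adult right-skewed distributions with medians near 32 / 28
    age = np.where(
        diseased,
        18.0 + rng.gamma(2.2, 6.5, size=n),
        18.0 + rng.gamma(2.0, 5.0, size=n),
    )
    age = np.clip(age, 18.0, 90.0)
    childbearing = female & (age < 50.0)
    pregnant = childbearing & (rng.random(n) < params.p_pregnant_given_childbearing)

    item_p = np.where(
        diseased[:, None],
        np.asarray(params.component_probs_diseased)[None, :],
        np.asarray(params.component_probs_healthy)[None, :],
    )
    items = rng.random((n, 8)) < item_p

    def imaging_latent(sens: float, spec: float, p_alt: float) -> np.ndarray:
        """POSITIVE/NEGATIVE by truth; for healthy patients part of the
        negative branch is an alternative-diagnosis finding."""
        u = rng.random(n)
        alt = rng.random(n) < p_alt
        out = np.empty(n, dtype=object)
        out[diseased] = np.where(
            u[diseased] < sens, TestResult.POSITIVE, TestResult.NEGATIVE
        )
        healthy = ~diseased
        neg_branch = u < spec
        out[healthy & ~neg_branch] = TestResult.POSITIVE
        out[healthy & neg_branch & alt] = TestResult.ALTERNATIVE_DX
        out[healthy & neg_branch & ~alt] = TestResult.NEGATIVE
        return out

    us = imaging_latent(params.us_sens, params.us_spec, params.p_us_alternative_dx_given_healthy)
    ct = imaging_latent(params.ct_sens, params.ct_spec, params.p_ct_alternative_dx_given_healthy)

    gyn_alt = (~diseased) & (rng.random(n) < params.p_gyn_alternative_dx)
    obs_resolves = (~diseased) & (rng.random(n) < params.p_obs_resolution_given_healthy)
    obs_clinical = diseased & (rng.random(n) < params.p_obs_clinical_aa_given_disease)

    width = max(4, len(str(n)))
    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"S{i + 1:0{width}d}",
                age_years=round(float(age[i]), 1),
                sex="F" if female[i] else "M",
                pregnant=bool(pregnant[i]),
                childbearing_age=bool(childbearing[i]),
                true_appendicitis=bool(diseased[i]),
                perforated=bool(perforated[i]),
                peritonitis=bool(peritonitis[i]),
                alvarado=AlvaradoComponents(*(bool(v) for v in items[i])),
                us_latent=us[i],
                ct_latent=ct[i],
                gyn_alternative_dx=bool(gyn_alt[i]) if (female[i] and childbearing[i]) else None,
                observation_resolves=bool(obs_resolves[i]),
                observation_clinical_aa=bool(obs_clinical[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# deterministic fixture cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Printed flow counts the fixture cohort must replay.

    ``observed_printed`` carries the narrative's "55 clinically observed"
    verbatim; it is arithmetically inconsistent with the same narrative's
    21 recoveries + 36 CT scans (= 57) and is therefore informational
    only — the replayed cohort observes 57 patients.
    """

    n: int = 183
    operated: int = 69
    operated_clinical: int = 27
    operated_ultrasound: int = 25
    operated_ct: int = 17
    diseased: int = 65
    negative_appendectomies: int = 4
    nar_female: int = 1
    nar_male: int = 3
    female_surgeries: int = 23
    male_surgeries: int = 46
    perforated: int = 17
    observed_printed: int = 55
    recovered: int = 21
    ct_total: int = 36
    ct_positive: int = 17
    ct_negative: int = 19  # includes the 9 alternative-diagnosis reads
    ct_alternative: int = 9
    discharged: int = 87
    alternative_total: int = 27
    females: int = 91
    females_diseased: int = 22
    males: int = 92
    males_diseased: int = 43

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated count identity."""
        identities = [
            ("operated_clinical + operated_ultrasound + operated_ct == operated",
             self.operated_clinical + self.operated_ultrasound + self.operated_ct == self.operated),
            ("ct_positive + ct_negative == ct_total",
             self.ct_positive + self.ct_negative == self.ct_total),
            ("operated + discharged + alternative_total == n",
             self.operated + self.discharged + self.alternative_total == self.n),
            ("females + males == n", self.females + self.males == self.n),
            ("females_diseased + males_diseased == diseased",
             self.females_diseased + self.males_diseased == self.diseased),
            ("female_surgeries + male_surgeries == operated",
             self.female_surgeries + self.male_surgeries == self.operated),
            ("nar_female + nar_male == negative_appendectomies",
             self.nar_female + self.nar_male == self.negative_appendectomies),
            ("diseased + negative_appendectomies == operated",
             self.diseased + self.negative_appendectomies == self.operated),
            ("females_diseased + nar_female == female_surgeries",
             self.females_diseased + self.nar_female == self.female_surgeries),
            ("males_diseased + nar_male == male_surgeries",
             self.males_diseased + self.nar_male == self.male_surgeries),
            ("operated_ct == ct_positive", self.operated_ct == self.ct_positive),
            ("ct_alternative <= ct_negative", self.ct_alternative <= self.ct_negative),
            ("perforated <= diseased", self.perforated <= self.diseased),
            ("recovered + ct_total + other exits <= n",
             self.recovered + self.ct_total
             + self.operated_clinical + self.operated_ultrasound
             <= self.n),
        ]
        for name, ok in identities:
            if not ok:
                raise ValueError(f"fixture spec violates identity: {name}")

    @property
    def observed(self) -> int:
        """Patients the replayed pathway admits for observation."""
        return self.recovered + self.ct_total

    @property
    def ct_negative_discharged(self) -> int:
        return self.ct_negative - self.ct_alternative

    @property
    def direct_discharges(self) -> int:
        return self.discharged - self.recovered - self.ct_negative_discharged

    @property
    def us_gyn_alternatives(self) -> int:
        return self.alternative_total - self.ct_alternative


def components_for_score(score: int) -> AlvaradoComponents:
    """A deterministic item pattern achieving a given total score.

    Items are switched on greedily in clinical-plausibility order
    (tenderness, leukocytosis, then the weight-1 items), which reaches
    every total in [0, 10].
    """
    if not 0 <= score <= 10:
        raise ValueError(f"score must lie in [0, 10], got {score}")
    order = [
        "tenderness_rlq",
        "leukocytosis",
        "nausea_vomiting",
        "migration_rlq",
        "anorexia",
        "rebound_pain",
        "temperature_gt_37_5",
        "neutrophils_gt_75",
    ]
    remaining = score
    chosen: dict[str, bool] = {item: False for item in _ITEMS}
    for item in order:
        w = ITEM_WEIGHTS[item]
        if remaining >= w:
            chosen[item] = True
            remaining -= w
    assert remaining == 0
    return AlvaradoComponents(**chosen)


def _largest_remainder(total: int, sizes: list[int]) -> list[int]:
    """Split ``total`` across groups proportionally to ``sizes``."""
    pool = sum(sizes)
    if pool == 0:
        return [0] * len(sizes)
    raw = [total * s / pool for s in sizes]
    base = [int(x) for x in raw]
    short = total - sum(base)
    order = sorted(range(len(sizes)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    for quota, size in zip(base, sizes):
        if quota > size:
            raise ValueError("cannot allocate more members than group size")
    return base


def build_fixture_cohort(spec: FixtureSpec | None = None) -> list[PatientRecord]:
    """Build the deterministic cohort replaying the printed flow.

    Running :func:`dialapp.pathway.run_cohort` on the result under the
    default configuration reproduces every count in ``spec``: surgery
    triggers 27/25/17, 4 negative appendectomies (1 F, 3 M, placed 2/2
    among the clinical- and ultrasound-trigger surgeries), 17
    perforations, 36 CT scans (17/10/9 positive/negative/alternative),
    87 discharges, 27 alternative-diagnosis exits, and the 91/92 sex
    split with 22/43 diseased.
    """
    if spec is None:
        spec = FixtureSpec()
    spec.validate()

    nar_clinical = spec.negative_appendectomies // 2
    nar_us = spec.negative_appendectomies - nar_clinical
    dis_clinical = spec.operated_clinical - nar_clinical
    dis_us = spec.operated_ultrasound - nar_us
    dis_ct = spec.operated_ct
    if dis_clinical + dis_us + dis_ct != spec.diseased:
        raise ValueError(
            "fixture spec violates identity: diseased surgeries by trigger "
            "must sum to the diseased total"
        )
    # female negative appendectomies go to the clinical-trigger stratum first
    nar_clin_f = min(spec.nar_female, nar_clinical)
    nar_us_f = spec.nar_female - nar_clin_f

    dis_f = _largest_remainder(spec.females_diseased, [dis_clinical, dis_us, dis_ct])

    records: list[PatientRecord] = []
    counter = {"i": 0}
    perforations_left = {"k": spec.perforated}

    def add(
        *,
        sex: str,
        diseased: bool,
        score: int,
        us: TestResult,
        ct: TestResult | None = None,
        peritonitis: bool = False,
        gyn_alt: bool | None = None,
        resolves: bool = False,
        clinical_aa: bool = False,
        age: float | None = None,
    ) -> None:
        counter["i"] += 1
        i = counter["i"]
        perforated = False
        if diseased and perforations_left["k"] > 0:
            perforated = True
            perforations_left["k"] -= 1
        if age is None:
            age = 19.0 + (i * 7) % 43  # deterministic adult ages, 19-61
        childbearing = sex == "F" and age < 50.0
        if childbearing and gyn_alt is None:
            gyn_alt = False
        if ct is None:
            ct = TestResult.POSITIVE if diseased else TestResult.NEGATIVE
        records.append(
            PatientRecord(
                patient_id=f"F{i:03d}",
                age_years=age,
                sex=sex,
                pregnant=False,
                childbearing_age=childbearing,
                true_appendicitis=diseased,
                perforated=perforated,
                peritonitis=peritonitis,
                alvarado=components_for_score(score),
                us_latent=us,
                ct_latent=ct,
                gyn_alternative_dx=gyn_alt if childbearing else None,
                observation_resolves=resolves,
                observation_clinical_aa=clinical_aa,
            )
        )

    # --- clinical-trigger surgeries: peritonitis or score above threshold
    for j in range(spec.operated_clinical):
        diseased = j < dis_clinical
        if diseased:
            sex = "F" if j < dis_f[0] else "M"
        else:
            sex = "F" if (j - dis_clinical) < nar_clin_f else "M"
        add(
            sex=sex,
            diseased=diseased,
            score=10 if j % 2 == 0 else 9,
            us=TestResult.NEGATIVE,
            peritonitis=(j % 4 == 0),
        )

    # --- ultrasound-trigger surgeries: positive ultrasound, score 5-8
    for j in range(spec.operated_ultrasound):
        diseased = j < dis_us
        if diseased:
            sex = "F" if j < dis_f[1] else "M"
        else:
            sex = "F" if (j - dis_us) < nar_us_f else "M"
        add(
            sex=sex,
            diseased=diseased,
            score=(5, 6, 7, 8)[j % 4],
            us=TestResult.POSITIVE,
        )

    # --- observed, CT-positive surgeries: all true cases, perfect CT
    for j in range(spec.operated_ct):
        sex = "F" if j < dis_f[2] else "M"
        add(sex=sex, diseased=True, score=(5, 6, 7, 8)[j % 4], us=TestResult.NEGATIVE)

    # --- non-operated strata (all disease-free)
    females_left = spec.females - (spec.females_diseased + spec.nar_female)
    gyn_alt_n = min(8, spec.us_gyn_alternatives, females_left)
    us_alt_n = spec.us_gyn_alternatives - gyn_alt_n
    strata = [
        ("recovered", spec.recovered),
        ("ct_negative", spec.ct_negative_discharged),
        ("ct_alternative", spec.ct_alternative),
        ("us_alternative", us_alt_n),
        ("direct_discharge", spec.direct_discharges),
    ]
    f_quota = _largest_remainder(females_left - gyn_alt_n, [n for _, n in strata])
    for (name, size), fq in zip(strata, f_quota):
        for j in range(size):
            sex = "F" if j < fq else "M"
            if name == "recovered":
                add(sex=sex, diseased=False, score=(5, 6, 7, 8)[j % 4],
                    us=TestResult.NEGATIVE, resolves=True)
            elif name == "ct_negative":
                add(sex=sex, diseased=False, score=(5, 6, 7, 8)[j % 4],
                    us=TestResult.NEGATIVE)
            elif name == "ct_alternative":
                add(sex=sex, diseased=False, score=(5, 6, 7, 8)[j % 4],
                    us=TestResult.NEGATIVE, ct=TestResult.ALTERNATIVE_DX)
            elif name == "us_alternative":
                add(sex=sex, diseased=False, score=(1, 2, 3, 4, 5)[j % 5],
                    us=TestResult.ALTERNATIVE_DX)
            else:  # direct discharge: low score, negative ultrasound
                add(sex=sex, diseased=False, score=(4, 3, 2, 1, 0)[j % 5],
                    us=TestResult.NEGATIVE)
    for j in range(gyn_alt_n):
        add(sex="F", diseased=False, score=(2, 3, 4)[j % 3],
            us=TestResult.NEGATIVE, gyn_alt=True, age=24.0 + j)

    if len(records) != spec.n:
        raise ValueError(
            "fixture spec violates identity: stratum sizes must sum to n "
            f"(got {len(records)} != {spec.n})"
        )
    n_f = sum(1 for r in records if r.sex == "F")
    if n_f != spec.females:
        raise ValueError(
            f"fixture spec violates identity: female total (got {n_f} != {spec.females})"
        )
    if perforations_left["k"] != 0:
        raise ValueError("fixture spec violates identity: perforations exceed diseased surgeries")
    return records


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

_BOOL_FIELDS = (
    "pregnant",
    "childbearing_age",
    "true_appendicitis",
    "perforated",
    "peritonitis",
    "observation_resolves",
    "observation_clinical_aa",
)

COHORT_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    *_BOOL_FIELDS[:5],
    *_ITEMS,
    "us_latent",
    "ct_latent",
    "gyn_alternative_dx",
    "observation_resolves",
    "observation_clinical_aa",
)


def write_cohort(records: list[PatientRecord], path) -> None:
    """Write a cohort to CSV, one row per patient."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "patient_id": r.patient_id,
            "age_years": r.age_years,
            "sex": r.sex,
        }
        for name in _BOOL_FIELDS[:5]:
            row[name] = getattr(r, name)
        row.update(r.alvarado.as_dict())
        row["us_latent"] = r.us_latent.value if r.us_latent else ""
        row["ct_latent"] = r.ct_latent.value if r.ct_latent else ""
        row["gyn_alternative_dx"] = (
            "" if r.gyn_alternative_dx is None else r.gyn_alternative_dx
        )
        row["observation_resolves"] = r.observation_resolves
        row["observation_clinical_aa"] = r.observation_clinical_aa
        rows.append(row)
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def _parse_bool(value: str, column: str) -> bool:
    if value in ("True", "true", "1"):
        return True
    if value in ("False", "false", "0"):
        return False
    raise ValueError(f"column {column!r}: expected boolean, got {value!r}")


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV; malformed rows raise with their row number."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file is missing columns: {missing}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        data = dict(zip(df.columns, row))
        try:
            items = {item: _parse_bool(data[item], item) for item in _ITEMS}
            gyn = data["gyn_alternative_dx"]
            records.append(
                PatientRecord(
                    patient_id=data["patient_id"],
                    age_years=float(data["age_years"]),
                    sex=data["sex"],
                    pregnant=_parse_bool(data["pregnant"], "pregnant"),
                    childbearing_age=_parse_bool(data["childbearing_age"], "childbearing_age"),
                    true_appendicitis=_parse_bool(data["true_appendicitis"], "true_appendicitis"),
                    perforated=_parse_bool(data["perforated"], "perforated"),
                    peritonitis=_parse_bool(data["peritonitis"], "peritonitis"),
                    alvarado=AlvaradoComponents(**items),
                    us_latent=TestResult(data["us_latent"]) if data["us_latent"] else None,
                    ct_latent=TestResult(data["ct_latent"]) if data["ct_latent"] else None,
                    gyn_alternative_dx=None if gyn == "" else _parse_bool(gyn, "gyn_alternative_dx"),
                    observation_resolves=_parse_bool(data["observation_resolves"], "observation_resolves"),
                    observation_clinical_aa=_parse_bool(
                        data["observation_clinical_aa"], "observation_clinical_aa"
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"cohort file row {idx}: {exc}") from exc
    return records
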