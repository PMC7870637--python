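"""Decision-engine behaviour: exits, triggers, traces, cost grouping."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dialapp.cohort import CohortParams, components_for_score, generate_cohort
from dialapp.pathway import (
    CareSetting,
    CostGroup,
    Disposition,
    PathwayConfig,
    PatientRecord,
    SurgeryTrigger,
    TestResult,
    UnresolvedLatentError,
    classify_cost_group,
    evaluate_patient,
    run_cohort,
)


def patient(
    *,
    score=6,
    sex="M",
    us=TestResult.NEGATIVE,
    ct=TestResult.NEGATIVE,
    peritonitis=False,
    diseased=False,
    pregnant=False,
    childbearing=False,
    gyn_alt=None,
    resolves=False,
    clinical_aa=False,
    pid="T001",
):
    if childbearing and gyn_alt is None:
        gyn_alt = False
    return PatientRecord(
        patient_id=pid,
        age_years=30,
        sex=sex,
        pregnant=pregnant,
        childbearing_age=childbearing,
        true_appendicitis=diseased,
        perforated=False,
        peritonitis=peritonitis,
        alvarado=components_for_score(score),
        us_latent=us,
        ct_latent=ct,
        gyn_alternative_dx=gyn_alt,
        observation_resolves=resolves,
        observation_clinical_aa=clinical_aa,
    )


class TestSingleExits:
    def test_peritonitis_goes_straight_to_surgery_without_ct(self):
        t = evaluate_patient(patient(peritonitis=True, score=6))
        assert t.disposition is Disposition.SURGERY
        assert t.surgery_trigger is SurgeryTrigger.CLINICAL
        assert "CT_or_MRI" not in t.tests_performed
        assert not t.observed

    def test_high_score_goes_to_surgery_clinically(self):
        t = evaluate_patient(patient(score=9))
        assert t.disposition is Disposition.SURGERY
        assert t.surgery_trigger is SurgeryTrigger.CLINICAL

    def test_positive_ultrasound_triggers_surgery(self):
        t = evaluate_patient(patient(score=6, us=TestResult.POSITIVE))
        assert t.surgery_trigger is SurgeryTrigger.ULTRASOUND

    def test_low_score_negative_ultrasound_discharged_without_admission(self):
        t = evaluate_patient(patient(score=3))
        assert t.disposition is Disposition.DISCHARGE
        assert t.tests_performed == {"US"}
        assert not t.observed

    def test_equivocal_with_positive_ct_operated_after_observation(self):
        t = evaluate_patient(patient(score=6, ct=TestResult.POSITIVE))
        assert t.disposition is Disposition.SURGERY
        assert t.surgery_trigger is SurgeryTrigger.CT
        assert t.observed
        assert t.imaging_label == "CT"

    def test_observation_resolution_is_discharged_without_imaging(self):
        t = evaluate_patient(patient(score=7, resolves=True))
        assert t.disposition is Disposition.DISCHARGE
        assert t.observed
        assert "CT_or_MRI" not in t.tests_performed

    def test_clinical_appendicitis_in_observation_beats_resolution(self):
        t = evaluate_patient(patient(score=7, resolves=True, clinical_aa=True))
        assert t.disposition is Disposition.SURGERY
        assert t.surgery_trigger is SurgeryTrigger.CLINICAL
        assert t.observed

    def test_gyn_alternative_diagnosis_exits_first(self):
        t = evaluate_patient(
            patient(sex="F", childbearing=True, gyn_alt=True, score=9, us=TestResult.POSITIVE)
        )
        assert t.disposition is Disposition.ALTERNATIVE_CARE
        assert t.tests_performed == {"GYN"}
        assert t.surgery_trigger is SurgeryTrigger.NONE

    def test_ultrasound_alternative_diagnosis_exits_before_surgery_rule(self):
        t = evaluate_patient(patient(score=9, us=TestResult.ALTERNATIVE_DX))
        assert t.disposition is Disposition.ALTERNATIVE_CARE

    def test_negative_ct_discharges_and_alternative_ct_redirects(self):
        assert (
            evaluate_patient(patient(score=6, ct=TestResult.NEGATIVE)).disposition
            is Disposition.DISCHARGE
        )
        assert (
            evaluate_patient(patient(score=6, ct=TestResult.ALTERNATIVE_DX)).disposition
            is Disposition.ALTERNATIVE_CARE
        )

    def test_pregnant_patient_gets_mri_label_with_same_logic(self):
        t = evaluate_patient(
            patient(
                sex="F", pregnant=True, childbearing=True, score=6,
                ct=TestResult.POSITIVE,
            )
        )
        assert t.imaging_label == "MRI"
        assert t.surgery_trigger is SurgeryTrigger.CT

    def test_unresolved_latent_raises(self):
        with pytest.raises(UnresolvedLatentError):
            evaluate_patient(patient(score=6, ct=None))
        with pytest.raises(UnresolvedLatentError):
            evaluate_patient(patient(sex="F", childbearing=True, us=None, gyn_alt=False))

    def test_determinism(self):
        a = evaluate_patient(patient(score=6, ct=TestResult.POSITIVE))
        b = evaluate_patient(patient(score=6, ct=TestResult.POSITIVE))
        assert dataclasses.asdict(a) == dataclasses.asdict(b)


class TestRecordInvariants:
    def test_perforation_requires_disease(self):
        with pytest.raises(ValueError):
            PatientRecord(
                patient_id="X", age_years=30, sex="M", pregnant=False,
                childbearing_age=False, true_appendicitis=False, perforated=True,
                peritonitis=False, alvarado=components_for_score(5),
            )

    def test_minors_rejected(self):
        with pytest.raises(ValueError):
            PatientRecord(
                patient_id="X", age_years=17, sex="M", pregnant=False,
                childbearing_age=False, true_appendicitis=False, perforated=False,
                peritonitis=False, alvarado=components_for_score(5),
            )

    def test_gyn_result_only_for_childbearing_females(self):
        with pytest.raises(ValueError):
            PatientRecord(
                patient_id="X", age_years=30, sex="M", pregnant=False,
                childbearing_age=False, true_appendicitis=False, perforated=False,
                peritonitis=False, alvarado=components_for_score(5),
                gyn_alternative_dx=False,
            )


class TestRunCohort:
    def test_single_peritonitis_patient(self):
        traces, summary = run_cohort([patient(peritonitis=True)])
        assert summary.operated == 1
        assert summary.discharged == summary.alternative_dx == 0

    def test_low_score_us_negative_patients_all_discharged(self):
        cohort = [patient(score=s % 5, pid=f"L{s}") for s in range(10)]
        _, summary = run_cohort(cohort)
        assert summary.operated == 0
        assert summary.discharged == 10
        assert summary.observed == 0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            run_cohort([patient(pid="A"), patient(pid="A")])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            run_cohort([])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15)
    def test_flow_conservation_on_random_cohorts(self, seed):
        """Surgery + discharge + alternative care exits partition any
        cohort; CT implies observation; triggers match dispositions."""
        records = generate_cohort(CohortParams(n_patients=120, seed=seed))
        traces, summary = run_cohort(records)
        assert summary.operated + summary.discharged + summary.alternative_dx == summary.n
        for t in traces:
            if "CT_or_MRI" in t.tests_performed:
                assert t.observed
            assert (t.surgery_trigger is SurgeryTrigger.NONE) == (
                t.disposition is not Disposition.SURGERY
            )

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=10)
    def test_low_stratum_negative_us_never_observed_or_operated(self, seed):
        records = generate_cohort(CohortParams(n_patients=150, seed=seed))
        traces, _ = run_cohort(records)
        by_id = {r.patient_id: r for r in records}
        for t in traces:
            r = by_id[t.patient_id]
            if (
                t.score <= 4
                and r.us_latent is TestResult.NEGATIVE
                and not r.peritonitis
                and t.disposition is not Disposition.ALTERNATIVE_CARE
            ):
                assert not t.observed
                assert t.disposition is Disposition.DISCHARGE


class TestCostGrouping:
    def test_surgery_with_ct_is_group_two(self):
        t = evaluate_patient(patient(score=6, ct=TestResult.POSITIVE))
        group, setting = classify_cost_group(t)
        assert group is CostGroup.G2_SURGERY_CT
        assert setting is CareSetting.HOSPITAL

    def test_surgery_without_ct_is_group_one(self):
        t = evaluate_patient(patient(score=9))
        assert classify_cost_group(t)[0] is CostGroup.G1_SURGERY_NO_CT

    def test_ct_discharge_is_group_three(self):
        t = evaluate_patient(patient(score=6, ct=TestResult.NEGATIVE))
        assert classify_cost_group(t)[0] is CostGroup.G3_CT_NO_SURGERY

    def test_direct_discharge_is_ambulatory_group_four(self):
        t = evaluate_patient(patient(score=2))
        group, setting = classify_cost_group(t)
        assert group is CostGroup.G4_NO_CT_NO_SURGERY
        assert setting is CareSetting.AMBULATORY

    def test_observed_discharge_without_ct_is_hospital_group_four(self):
        t = evaluate_patient(patient(score=6, resolves=True))
        group, setting = classify_cost_group(t)
        assert group is CostGroup.G4_NO_CT_NO_SURGERY
        assert setting is CareSetting.HOSPITAL
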