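"""Diagnostic-accuracy statistics: 2x2 panels, exact intervals, ROC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dialapp.diagnostics import (
    ConfusionMatrix,
    clopper_pearson,
    cohort_rates,
    confusion_from_traces,
    performance,
    reconstruct_counts,
    roc_analysis,
    round_half_up,
)
from dialapp.cohort import components_for_score
from dialapp.pathway import PatientRecord, TestResult, evaluate_patient, run_cohort


def cp_f_oracle(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Independent Clopper-Pearson bounds via the F-distribution
    formulation of the exact binomial interval."""
    alpha = 1 - level
    if k == 0:
        low = 0.0
    else:
        f = stats.f.ppf(alpha / 2, 2 * k, 2 * (n - k + 1))
        low = k * f / (n - k + 1 + k * f)
    if k == n:
        high = 1.0
    else:
        f = stats.f.ppf(1 - alpha / 2, 2 * (k + 1), 2 * (n - k))
        high = (k + 1) * f / (n - k + (k + 1) * f)
    return 100 * low, 100 * high


def concordance_auc(scores, truths) -> float:
    """O(n^2) pairwise Mann-Whitney concordance, ties counted 1/2."""
    pos = [s for s, t in zip(scores, truths) if t]
    neg = [s for s, t in zip(scores, truths) if not t]
    total = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return total / (len(pos) * len(neg))


class TestPerformance:
    def test_pathway_cells(self):
        r = performance(ConfusionMatrix(65, 4, 0, 114))
        assert r.sensitivity.rounded() == 100.0
        assert r.specificity.rounded() == 96.6
        assert r.ppv.rounded() == 94.2
        assert r.npv.rounded() == 100.0
        assert r.accuracy.rounded() == 97.8

    def test_degenerate_all_correct(self):
        r = performance(ConfusionMatrix(1, 0, 0, 1))
        assert all(m.rounded() == 100.0 for m in r.metrics().values())

    def test_score_classifier_ppv(self):
        assert performance(ConfusionMatrix(48, 14, 17, 104)).ppv.rounded() == 77.4

    def test_zero_denominator_metric_is_undefined_not_zero(self):
        r = performance(ConfusionMatrix(0, 2, 0, 3))  # no diseased patients
        assert r.sensitivity.estimate_pct is None
        assert r.specificity.estimate_pct is not None

    def test_estimate_always_inside_its_interval(self):
        for cm in [ConfusionMatrix(65, 4, 0, 114), ConfusionMatrix(3, 5, 2, 7)]:
            for m in performance(cm).metrics().values():
                assert m.ci_low_pct - 1e-9 <= m.estimate_pct <= m.ci_high_pct + 1e-9


class TestClopperPearson:
    def test_all_successes_closed_form_lower_bound(self):
        low, high = clopper_pearson(65, 65)
        assert high == 100.0
        assert low == pytest.approx(100 * 0.025 ** (1 / 65), abs=1e-9)

    def test_zero_successes_pins_lower_bound(self):
        low, high = clopper_pearson(0, 10)
        assert low == 0.0
        assert high > 0

    @given(st.integers(1, 400).flatmap(lambda n: st.tuples(st.just(n), st.integers(0, n))))
    @settings(max_examples=60)
    def test_matches_f_distribution_oracle_and_contains_estimate(self, kn):
        n, k = kn
        low, high = clopper_pearson(k, n)
        olow, ohigh = cp_f_oracle(k, n)
        assert low == pytest.approx(olow, abs=1e-7)
        assert high == pytest.approx(ohigh, abs=1e-7)
        assert low - 1e-9 <= 100 * k / n <= high + 1e-9

    def test_interval_narrows_with_sample_size(self):
        widths = []
        for n in (20, 80, 320):
            low, high = clopper_pearson(n // 2, n)
            widths.append(high - low)
        assert widths == sorted(widths, reverse=True)

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)


class TestReconstructCounts:
    def test_pathway_reconstruction(self):
        rec = reconstruct_counts(100, 96.6, 65, 118)
        assert rec.matrix.as_tuple() == (65, 4, 0, 114)
        assert not rec.roundtrip_warning

    def test_score_classifier_reconstruction_flags_rounding_drift(self):
        rec = reconstruct_counts(73.9, 88.1, 65, 118)
        assert rec.matrix.as_tuple() == (48, 14, 17, 104)
        # 48/65 displays as 73.8, not the published 73.9
        assert rec.roundtrip_warning

    def test_perfect_inputs(self):
        rec = reconstruct_counts(100, 100, 10, 10)
        assert rec.matrix.as_tuple() == (10, 0, 0, 10)
        assert not rec.roundtrip_warning

    @given(st.integers(10, 200), st.integers(10, 200), st.integers(0, 100), st.integers(0, 100))
    @settings(max_examples=50)
    def test_unflagged_reconstructions_round_trip(self, nd, nh, ks, kc):
        """performance o reconstruct_counts re-derives sens/spec to one
        decimal whenever the warning flag is unset."""
        sens = round_half_up(100 * min(ks, nd) / nd, 1)
        spec = round_half_up(100 * min(kc, nh) / nh, 1)
        rec = reconstruct_counts(sens, spec, nd, nh)
        if not rec.roundtrip_warning:
            perf = performance(rec.matrix)
            assert perf.sensitivity.rounded() == sens
            assert perf.specificity.rounded() == spec


class TestRoc:
    def test_perfect_separation(self):
        assert roc_analysis([10] * 4 + [0] * 4, [True] * 4 + [False] * 4).auc == 1.0

    def test_uninformative_score(self):
        assert roc_analysis([5] * 6, [True] * 3 + [False] * 3).auc == 0.5

    def test_small_example_matches_concordance_oracle(self):
        r = roc_analysis([3, 5, 7, 9], [False, False, True, True])
        assert r.auc == concordance_auc([3, 5, 7, 9], [False, False, True, True])
        assert r.youden_optimal_cutoff == 6.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40)
    def test_trapezoid_auc_equals_concordance_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.integers(0, 11, n).tolist()
        truths = (rng.random(n) < 0.5).tolist()
        if all(truths) or not any(truths):
            truths[0] = not truths[0]
        r = roc_analysis(scores, truths)
        assert r.auc == pytest.approx(concordance_auc(scores, truths), abs=1e-12)

    def test_curve_monotone_along_sweep(self):
        rng = np.random.default_rng(4)
        scores = rng.integers(0, 11, 60).tolist()
        truths = (rng.random(60) < 0.4).tolist()
        r = roc_analysis(scores, truths)
        # raising the cutoff can only lower sensitivity and raise specificity
        assert list(r.sensitivities) == sorted(r.sensitivities, reverse=True)
        assert list(r.specificities) == sorted(r.specificities)

    def test_cutoffs_are_half_integers(self):
        r = roc_analysis([2, 4, 5, 7], [False, False, True, True])
        assert all(abs(c * 2 - round(c * 2)) < 1e-12 for c in r.thresholds)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [True, True, True])


class TestConfusionAndRates:
    def test_single_true_positive(self, fixture_records):
        record = fixture_records[0]  # diseased, operated clinically
        trace = evaluate_patient(record)
        cm = confusion_from_traces([trace], [record], "pathway_surgery")
        assert cm.as_tuple() == (1, 0, 0, 0)

    def test_id_mismatch_rejected(self, fixture_records):
        trace = evaluate_patient(fixture_records[0])
        with pytest.raises(ValueError, match="no matching record"):
            confusion_from_traces([trace], fixture_records[1:3], "pathway_surgery")

    def test_fixture_rates(self, fixture_run):
        records, traces, _ = fixture_run
        rates = cohort_rates(traces, records)
        assert rates.nar_pct == 5.8
        assert rates.ct_rate_pct == 19.7
        assert rates.nar_male_pct == 6.5
        # printed as 4.4% but 1/23 rounds to 4.3
        assert rates.nar_female_pct == 4.3

    def test_no_surgery_cohort_has_undefined_nar(self):
        record = PatientRecord(
            patient_id="D1", age_years=25, sex="M", pregnant=False,
            childbearing_age=False, true_appendicitis=False, perforated=False,
            peritonitis=False, alvarado=components_for_score(2),
            us_latent=TestResult.NEGATIVE, ct_latent=TestResult.NEGATIVE,
        )
        traces, _ = run_cohort([record])
        rates = cohort_rates(traces, [record])
        assert rates.nar_pct is None
        assert rates.discharge_rate_pct == 100.0

    def test_ct_rule_counts_only_imaged_patients(self, fixture_run):
        records, traces, _ = fixture_run
        cm = confusion_from_traces(traces, records, "ct_positive")
        assert cm.as_tuple() == (17, 0, 0, 19)
        cm_us = confusion_from_traces(traces, records, "us_positive")
        # ultrasound performed in everyone except gynecological exits
        assert cm_us.n == 175
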