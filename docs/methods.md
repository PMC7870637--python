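# Methods

## The decision model

`dialapp` is an executable model of a risk-stratified diagnostic pathway
for adults presenting with suspected acute appendicitis. The pathway
combines five elements: the Alvarado score, routine surgeon-performed
abdominal ultrasound, a gynecological consultation for women of
childbearing age, in-hospital observation with clinical re-evaluation
for the equivocal middle band, and cross-sectional imaging (CT, or MRI
in pregnancy) reserved for patients whose complaints persist under
observation.

The Alvarado score is the weighted sum of eight binary items —
migration of pain to the right lower quadrant (1), anorexia (1),
nausea/vomiting (1), right-lower-quadrant tenderness (2), rebound pain
(1), temperature > 37.5 °C (1), leukocytosis (2), neutrophils > 75%
(1) — giving an integer in [0, 10]. Triage reads the score in three
bands: ≤ 4 (discharge if ultrasound is negative), 5–8 (observe), ≥ 9
(advise appendectomy). The band edges are configurable
(`RiskThresholds`) because the score is also used as a standalone
classifier at the different cutoff "> 7", and both conventions must
coexist.

`evaluate_patient` applies the rules in a fixed order so that every
patient reaches exactly one disposition:

1. gynecological consultation (childbearing-age women): an alternative
   gynecological diagnosis exits to alternative care;
2. ultrasound: an alternative-diagnosis finding exits to alternative
   care;
3. surgery rule: peritonitis, score ≥ 9, or positive ultrasound →
   surgery (trigger recorded as clinical or ultrasound);
4. discharge rule: score ≤ 4 with negative ultrasound → discharge;
5. observation (score 5–8, inconclusive ultrasound): clinically evident
   appendicitis → surgery; resolution of complaints → discharge;
   otherwise CT/MRI, whose result decides surgery, discharge, or
   alternative care.

The intake elements are in reality a simultaneous bundle; fixing the
order makes traces reproducible and does not change any disposition,
because all decisions are functions of pre-drawn latent results. Each
patient carries a *latent* result for every test (what the test would
show if ordered); the engine reads a latent only when the pathway
orders the test. This is what makes selective-imaging rates (e.g. the
fraction of patients ever receiving CT) well-defined model outputs
rather than inputs. The engine is a pure function of
(record, configuration).

Observation is modelled by two pre-drawn booleans — clinically evident
appendicitis, and symptom resolution — with imaging for the remainder.
No time-to-event structure is modelled; the protocol's "re-evaluation
within 24 h" is carried as an informational parameter only. MRI in
pregnancy is the CT node with a different label and identical operating
characteristics.

## Synthetic cohorts

### Stochastic generator

`generate_cohort` draws independent patients with the marginal
structure of the validation cohort the package emulates:

| parameter | default | meaning |
|---|---|---|
| `p_female` | 91/183 | cohort sex split |
| `disease_given_female` / `male` | 22/91, 43/92 | appendicitis risk by sex (marginal prevalence 65/183 ≈ 35.5%) |
| `perforation_given_disease` | 17/65 | perforation among true cases |
| `us_sens` / `us_spec` | 0.582 / 0.973 | surgeon-performed ultrasound |
| `ct_sens` / `ct_spec` | 1.0 / 1.0 | CT (and MRI) operating characteristics |
| `p_us_alternative_dx_given_healthy` | 0.08 | alternative finding inside the negative branch, non-cases only |
| `p_ct_alternative_dx_given_healthy` | 9/19 | same for CT (matches the observed 9 of 19 non-positive scans) |
| `p_gyn_alternative_dx` | 0.10 | gynecological alternative diagnosis, healthy childbearing women |
| `p_peritonitis_given_disease` | 0.15 | direct-to-surgery peritonitis flag |
| `p_obs_resolution_given_healthy` | 21/40 | symptom resolution under observation (non-cases) |
| `p_obs_clinical_aa_given_disease` | 0.25 | clinically evident appendicitis during observation (cases) |

Alternative-diagnosis imaging findings are modelled as a sub-outcome of
the negative branch and only for patients without appendicitis,
matching how such exits are reported. Diseased patients never resolve
under observation and healthy patients never develop clinically evident
appendicitis — a deliberate simplification that, combined with perfect
CT, makes the pathway's false-negative rate exactly zero, as in the
cohort being emulated.

The eight score items are independent Bernoulli draws conditional on
disease. Only the medians of the resulting score (7 with disease, 4
without) are constrained by the emulated cohort; the itemwise
probabilities are free parameters chosen once on clinical plausibility
(tenderness nearly universal in disease, laboratory signs common, every
item rarer without disease) and verified by simulation
(`scripts/calibrate_components.py`). An emergent property of this
calibration, computed by the acceptance script rather than imposed, is
a simulated score ROC with AUC ≈ 0.92 and Youden-optimal cutoff 5.5.

Ages are drawn from shifted gamma families (medians near 32/28 years
for cases/non-cases) purely for realism: the engine never reads age
except through the childbearing flag (female, age < 50). BMI and
laboratory values are not generated — the engine consumes
pre-dichotomized items, so continuous covariates would be decoration.

What the generator does **not** emulate: correlation between score
items, secular time structure, protocol violations and exclusions, loss
to follow-up, and any dependence of test accuracy on disease severity.
Passing simulation tests therefore shows internal consistency of the
model at the stated operating characteristics, not external validity on
real patients.

### Deterministic fixture

`build_fixture_cohort` constructs 183 patients such that the engine
replays a published patient flow *exactly*: 69 appendectomies — 27
clinical-trigger, 25 ultrasound-trigger, 17 CT-trigger — with 4 negative
appendectomies (1 of 23 female surgeries, 3 of 46 male) placed 2/2 among
the clinical- and ultrasound-trigger strata (CT is perfect, so none can
sit there); all 65 true cases operated, 17 of them perforated; 36 CT
scans (17 positive, 10 negative discharges, 9 alternative diagnoses);
87 discharges; 27 alternative-diagnosis exits (9 CT, 18 ultrasound/
gynecology, split 10/8 — the source does not break these down); 91
women (22 diseased) and 92 men (43 diseased). `FixtureSpec.validate()`
checks the count identities and names the first violated one.

One printed count cannot be honoured: the narrative reports 55 observed
patients, but its own 21 recoveries plus 36 CT scans force 57, and flow
conservation (183 = 69 + 87 + 27 exits with 56 direct discharges and 18
pre-observation alternative exits) leaves no room to reconcile. The
fixture observes 57; the discrepancy is carried in
`diagnostics.KNOWN_DISCREPANCIES` and surfaced as a warning in every
report run. Similarly, the female NAR of 1/23 displays as 4.3%, not the
printed 4.4%.

## Diagnostic accuracy

2×2 matrices are counted against latent disease truth under a named
positivity rule. The whole-pathway rule calls surgery positive and both
discharge and alternative care negative, which yields TP 65 / FP 4 /
FN 0 / TN 114 on the fixture. Test-specific rules (ultrasound, CT)
count only patients in whom the pathway performed the test.

Confidence intervals are Clopper–Pearson exact (beta-quantile form),
chosen because the emulated report shows 100% estimates with
non-degenerate lower bounds, which rules out Wald-type intervals; the
test suite cross-checks against the independent F-distribution form.
Display rounding is half-up to one decimal; full precision is kept
internally. A metric with an empty denominator is undefined (`None`),
never zero.

`reconstruct_counts` inverts published sensitivity/specificity
percentages to integer cells (nearest count) and flags reconstructions
that fail to re-derive their inputs at display precision. Two published
cells of the score-classifier column (accuracy 82.3%, NPV 85.9%) fail
this round-trip against their own reconstructed counts (83.1%, 86.0%)
and are treated as known discrepancies, not as targets.

ROC analysis sweeps every half-integer cutoff between adjacent observed
scores (plus the two degenerate end cutoffs), calling positive above
the cutoff. The trapezoid AUC over this sweep equals the pairwise
Mann–Whitney concordance with ties counted ½ — asserted exactly against
an O(n²) oracle. Tied false-positive-rate points are ordered by true
positive rate so vertical curve segments contribute zero width. The
Youden cutoff maximises sensitivity + specificity − 1; ties break
toward the lower (more sensitive) cutoff.

## Cost model

Four utilisation groups with fixed per-case tariffs (EUR): surgery
without CT 1317, surgery with CT 1434, CT without surgery 675, neither
558 in hospital or 250 ambulatory (only for patients never admitted).
A scenario is a proportion vector over these groups, a tariff table,
and a case volume (default 100,000 suspected presentations);
`total_cost` is the obvious bilinear form and `scenario_saving` the
signed difference.

The published scenario proportion sets are bundled verbatim
(`PAPER_SCENARIOS`). Their published *totals* are not derivable from
those proportions and tariffs (e.g. 0.59·1317 + 0.19·1434 + 0.22·675
≈ 1198 EUR/case → 119.8 M€, against a printed 119.2 M€), so the
arithmetic engine, not the printed totals, is the contract; reports
show the recomputed values. Pricing the two four-group sets gives
90.2 vs 83.4 M€ per 100,000 cases — a recomputed saving of 6.7 M€.
The three-group "pre-pathway" set (0.52/0.17/0.19) sums to 0.88 and is
evidently a count triple (52/17/19 of 88) rather than a proportion set;
it is stored as printed and its recomputed total should not be read as
a historical estimate.

Empirical proportions from a cohort run come in two denominators: all
patients (with the no-CT/no-surgery group split by care setting), or
only patients with CT or surgery (the published three-group
convention). On the fixture the latter gives 52/88, 17/88, 19/88.

## Numerical and testing choices

- All randomness flows through one `numpy` `default_rng(seed)` per
  generated cohort; identical seeds give identical cohorts.
- Rounding is half away from zero via `decimal`, because banker's
  rounding disagrees with the emulated report's display convention.
- Problem sizes: property tests use cohorts of 120–150 patients over
  seeded Hypothesis draws; distributional checks use 20,000 patients at
  a Bonferroni-adjusted exact-binomial level (three simultaneous
  checks); the headline simulation check uses 50,000 patients at exact
  99% binomial bounds per characteristic. These sizes put Monte-Carlo
  error well below the tolerances being asserted.
- Degenerate inputs are errors, not silent defaults: unresolved latent
  results when a test is ordered, duplicate patient identifiers, empty
  cohorts, single-class ROC inputs, zero-surgery NAR denominators
  (reported as undefined), and inconsistent fixture counts.

## Known limitations

- Item independence overstates the score's variance structure; real
  Alvarado items are positively correlated.
- The observation phase has no time axis; length-of-stay and
  time-to-operation endpoints are out of scope.
- Perforation is generated but does not feed back into test accuracy or
  observation behaviour.
- The cost model is a static extrapolation at fixed tariffs; no
  discounting, no sensitivity analysis beyond proportion perturbation.
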