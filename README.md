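# dialapp

An executable model of a risk-stratified diagnostic pathway for adults
presenting with suspected acute appendicitis, aimed at surgeons,
clinical epidemiologists, and health-economics analysts who want to
study how selective imaging policies trade off the negative
appendectomy rate (NAR), CT utilisation, and cost.

The pathway combines the Alvarado score, routine ultrasound, a
gynecological consultation for women of childbearing age, observation
with clinical re-evaluation for the equivocal band, and CT (MRI in
pregnancy) only for complaints that persist under observation. The
package provides:

- **`dialapp.alvarado`** — the 10-point score
  `S = 1·migration + 1·anorexia + 1·nausea + 2·tenderness + 1·rebound +
  1·temp + 2·leukocytosis + 1·neutrophils` and its management bands
  (≤ 4 low, 5–8 intermediate, ≥ 9 high; configurable);
- **`dialapp.pathway`** — a pure decision engine that orders tests
  lazily from pre-drawn latent results and ends every patient in
  exactly one disposition (surgery / discharge / alternative care) with
  a full trace;
- **`dialapp.cohort`** — a seeded stochastic patient generator
  (prevalence 65/183, ultrasound Se/Sp 0.582/0.973, perfect CT, score
  medians 7 vs 4 by disease status) and a deterministic 183-patient
  fixture cohort that replays a published validation flow exactly;
- **`dialapp.diagnostics`** — 2×2 metrics with exact Clopper–Pearson
  intervals, count reconstruction from printed percentages, ROC/AUC
  with Youden cutoff, and cohort outcome rates;
- **`dialapp.costs`** — the four-group CT-by-surgery cost model
  (1317/1434/675/558 or 250 € per case) with scenario differencing.

## Worked example

Score a patient with nausea, right-lower-quadrant tenderness, fever and
leukocytosis:

```
$ dialapp score --nausea --tenderness --temperature --leukocytosis
Alvarado score: 6/10
Risk stratum: INTERMEDIATE
```

An intermediate-band patient is admitted for observation rather than
operated or discharged. Replaying the deterministic validation cohort
and inspecting the outcome rates:

```
$ dialapp replay-fixture --out out/
$ column -s, -t out/rates.csv
rate                          pct   numerator  denominator
negative_appendectomy         5.8   4          69
perforation                   24.6  17         69
ct                            19.7  36         183
appendectomy                  37.7  69         183
discharge                     47.5  87         183
negative_appendectomy_female  4.3   1          23
negative_appendectomy_male    6.5   3          46
```

Read: of 183 patients, 69 (37.7%) underwent appendectomy of which 4
(5.8%) were negative — i.e. the specimen showed no acute inflammation —
only 36 patients (19.7%) ever received a CT scan, and 87 (47.5%) were
discharged without surgery. The whole-pathway diagnostic performance
(positive call = surgery) from `out/performance.csv`:

```
instrument            metric       estimate_pct  ci_low_pct  ci_high_pct
diagnostic_algorithm  sensitivity  100.0         94.5        100.0
diagnostic_algorithm  specificity  96.6          91.5        99.1
diagnostic_algorithm  ppv          94.2          85.8        98.4
diagnostic_algorithm  npv          100.0         96.8        100.0
diagnostic_algorithm  accuracy     97.8          94.5        99.4
```

No true case is missed (sensitivity 100%, 65/65) at the price of 4
false-positive operations among 118 disease-free patients (specificity
96.6%). Stochastic cohorts with the same statistical structure come
from `dialapp simulate --n 50000 --seed 1 --out sim/`, whose
`recovery.csv` compares estimated test characteristics with the
generating parameters.

The same API is available in Python:

```python
from dialapp import build_fixture_cohort, run_cohort, cohort_rates

records = build_fixture_cohort()
traces, summary = run_cohort(records)
print(summary.operated, summary.ct_performed)   # 69 36
print(cohort_rates(traces, records).nar_pct)    # 5.8
```

Some published cells are arithmetically inconsistent with their own
counts (see `dialapp.diagnostics.KNOWN_DISCREPANCIES`); every report
run logs them, and `docs/methods.md` discusses each one.

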