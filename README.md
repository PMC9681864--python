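# veicans

EEG-based grading of CAR-T neurotoxicity severity.

Immune effector cell-associated neurotoxicity syndrome (ICANS) is a common,
sometimes severe complication of CAR-T cell therapy, graded 0–4 at the
bedside from the ICE cognitive exam and four neurological domains. The EEG
of an encephalopathic patient changes in visually obvious ways — background
slowing into theta and delta frequencies, loss of the posterior dominant
rhythm, generalized periodic discharges, voltage attenuation — and the
VE-ICANS score turns those qualitative readings into a single number: each
feature carries an integer point value and the score of a patient-day is the
sum of the points of the features present, with four severe patterns (NCSE,
extreme low voltage / electrocerebral silence, burst suppression, unreactive
EEG) forcing the maximal score outright.

This package provides, for neurophysiology and cellular-therapy researchers:

- **`veicans.features`** — the published VE-ICANS scoring table, the
  binary EEG-feature vocabulary (slowing binned in 1 Hz steps), the scorer,
  table admissibility checks, and file formats for tables and patient-day
  feature matrices.
- **`veicans.ltr`** — the procedure that derives such tables from data:
  pairwise learning-to-rank with a logistic loss over all pairs of
  patient-days with different ICANS grades, an ElasticNet penalty, sign
  constraints (abnormal features ≥ 0, normal ≤ 0), ordinal constraints
  (slower slowing never scores less), a minimum-prevalence filter (≥ 5
  occurrences), and integerisation of the fitted coefficients into bedside
  point values.
- **`veicans.evaluation`** — grouped, grade-stratified nested
  cross-validation (all days of a patient stay in one fold), Pearson
  correlation with 1000-replicate bootstrap CIs, discrimination AUC for
  grade 0 vs ≥ x as the Mann–Whitney rank statistic, Yates-corrected
  chi-square and Mann–Whitney U cohort tests, and the feature Spearman
  correlation matrix.
- **`veicans.clinical`** — ICE score assembly from chart findings with the
  standard substitution rules, ICANS grade assembly by the ASTCT max rule,
  reviewer reconciliation (discrepancies average), and inter-rater
  agreement statistics.
- **`veicans.simulate`** — a synthetic cohort generator (sticky Markov
  grade trajectories, latent-severity feature emissions calibrated to the
  published cohort prevalences) so the whole pipeline runs end-to-end with
  no patient data.

The pairwise ranking model minimises, over coefficients *w* with no
intercept,

    (1/N) Σ_pairs log(1 + exp(−wᵀ(x_hi − x_lo)))  +  λ(α‖w‖₁ + (1−α)‖w‖₂²/2)

subject to the sign and ordinal constraints above, where each pair orients a
higher-graded day against a lower-graded one and exact grade ties are
dropped; 315 patient-days expand to tens of thousands of training pairs.

## Worked example

```python
import veicans as v

table = v.default_table()
v.score({"delta_le_1": 1}, table).value          # 10
v.score({"pdr": 1}, table).value                 # -1
v.score({"delta_1_2": 1, "gpds": 1, "theta_4_5": 1}, table).value  # 10
v.score({"burst_suppression": 1}, table)
# VEICANSScore(value=18, severe_override=True, ...)

# simulate a cohort, re-derive a table, evaluate it out of sample
cohort = v.sample_cohort(v.default_cohort_spec(seed=1))
report = v.nested_cv(cohort.records, v.EvalConfig(seed=1))
print(round(report.pearson_r, 2), [round(x, 2) for x in report.pearson_ci])
# 0.69 [0.63, 0.74]
print({lvl: round(auc, 2) for lvl, (auc, lo, hi) in report.auc.items()})
# {1: 0.95, 2: 0.97, 3: 0.99, 4: 1.0}
```

A grade-0 day with a delta ≤ 1 Hz background scores 10/18 — deep delta
slowing alone already marks a severely abnormal EEG — while a normal awake
record with a PDR and alpha ≥ 9 Hz scores −2.

The same pipeline from the shell:

```
veicans simulate --out cohort.csv --seed 1
veicans score    --input cohort.csv --out scored.csv
veicans train    --input cohort.csv --out mytable.json --seed 1
veicans stats    --out table1_stats.csv     # packaged 2x2 cohort rows
```

`veicans stats` recomputes the cohort contingency tests; e.g. generalized
periodic discharges, present 2/156 mild-ICANS days vs 14/159 severe-ICANS
days, give a continuity-corrected chi-square p = 0.0054.

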