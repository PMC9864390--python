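# si-pheno — statin-intolerance phenotyping and prevalence estimation

Statin intolerance (SI) — most often statin-associated muscle symptoms
(SAMS) — has no universally accepted operational definition, so its
prevalence in routine care is uncertain. This project implements a complete
phenotyping pipeline for longitudinal outpatient EMR extracts (dated ICD-10
diagnoses and ATC-coded prescriptions) that

1. applies a clinical rule table to classify every eligible patient into
   one of five labels — *tolerant*, *absolute* SI (permanent statin
   discontinuation) or *partial* SI (still on statins), each at *high* or
   *low* confidence — from seven signal events: statin down-titration
   (same or different molecule), switch / multi-statin use, long-term
   (>180-day) discontinuation, intermittent dosing (medication-possession
   ratio < 0.5), exclusive low-dose use, a documented intolerance note,
   and SAMS diagnosis codes; and
2. calibrates the estimate with supervised learning: for each class a
   high-confidence-vs-tolerant classifier (logistic regression, LightGBM
   and XGBoost compared by F1 under stratified 4-fold CV) is thresholded
   where precision = recall (equivalently FP = FN) on out-of-fold scores,
   then reclassifies the low-confidence patients, moving predicted
   intolerant patients into the high-confidence row while conserving the
   total.

Features for the models follow standard claims-data practice: presence and
counts per 3-character ICD group and ATC level-4 class, demographics, and
utilization (prescription, molecule and visit-day counts), screened by
mutual information with the target (plug-in estimator for discrete
features, k-nearest-neighbour entropy estimator for continuous ones).

Because real claims data cannot be redistributed, the package ships a
synthetic EMR generator (`si_pheno.synthetic_emr`) that plants the five
phenotypes as prescription/diagnosis trajectories, plants a latent
intolerance indicator among low-confidence patients, and gives truly
intolerant patients rate-ratio-elevated myalgia/cramp codes, fibrate
co-prescription and physician-visit counts — the signal the calibration
step must find. Every downstream stage is validated end-to-end against
this planted truth.

## Worked example

```bash
python analysis/01_simulate_cohort.py        # 20,000 patients, seed 2017
python analysis/02_rule_classification.py
python analysis/03_feature_selection.py
python analysis/04_ml_calibration.py
python analysis/05_prevalence_tables.py
```

The rule stage on the simulated cohort prints

```
        label  count
     tolerant  14510
absolute_high   1350
 absolute_low   1799
 partial_high   1221
  partial_low   1120
planted-label recovery under default noise: 95.9%
```

(recovery is exact only when random muscle-symptom codes are switched off —
an incidental myalgia code *is* a genuine sign event). Calibration then
moves 515 absolute and 647 partial low-confidence patients upward:

```
post-ML high-confidence share 18.7% vs planted latent share 20.4% (error -1.7pp)
```

i.e. the precision=recall thresholding recovers the planted share of truly
intolerant low-confidence patients to within ~2 percentage points.

`analysis/05_prevalence_tables.py` runs the same prevalence arithmetic on
the reference German outpatient cohort it was designed for (292,603
eligible patients): absolute high-confidence prevalence rises 6.4% → 8.1%
(+26.6%), partial 2.8% → 4.4% (+57.1%), high-confidence total 12.5%, total
SI bound 24.3%, with tolerant, total and combined SI counts unchanged.

## Command-line interface

`si-pheno simulate|validate|classify|run` wraps the same library calls for
shell use; `si-pheno run --out <dir>` writes `prevalence.csv`,
`characteristics.csv`, first-event down-titration/switch matrices,
`attrition.csv`, `model_report.json` and a run manifest.

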