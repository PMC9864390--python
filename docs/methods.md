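# Methods

## Study design

The pipeline models a retrospective outpatient cohort design with a fixed
observation window: a three-year **study period** (default 2017-03-01 to
2020-03-31) containing a one-year **selection period** (2019-03-01 to
2020-03-31). Each patient's **index date** is the latest statin
prescription in the study period; patients on non-statin lipid-lowering
therapy (LLT) only are anchored at their latest non-statin LLT
prescription. Events are assessed in a **lookback window**
`[max(study_start, index − 730 d), index]`. All intervals are half-open
`[start, end)` and dates are ISO-8601; this removes off-by-one ambiguity
in every gap and window computation.

Eligibility requires, in order: age ≥ 18 at index (ages are computed from
birth year only, as EMR birth dates are anonymized to year); ≥ 1
consultation in the selection period (any dated event — the source records
visits by date, so recorded activity operationalizes "consultation"); ≥ 1
LLT prescription (ATC `C10*`) in the study period; and ≥ 1 qualifying
diagnosis (ASCVD, high CV risk, or hypercholesterolemia) at any time. The
attrition report counts removals per step in that order.

The shipped ICD-10/ATC prefix sets (ASCVD = I20–I25, I63, I65, I66, I70,
I73.9; high CV risk = E10, E11; hypercholesterolemia = E78.0/.2/.4/.5;
SAMS = M79.1, M60.8/.9, G72.0/.9, R25.2) are conventional stand-ins and
fully config-overridable; real deployments should substitute their own
validated code lists.

## Signal events and the rule table

Seven event detectors run over each patient's statin exposure (ATC
`C10AA*`, plus the statin component of `C10B*` fixed combinations) in the
lookback:

* **Down-titration** — consecutive scripts with the same molecule at a
  strictly lower dose, or a molecule change to a strictly lower intensity
  band. The intensity banding (low/moderate/high per molecule and dose) is
  the conventional one and ships as editable package data.
* **Switch** — a molecule change at unchanged intensity. **Multi-statin
  use** requires ≥ 2 molecules *and* ≥ 2 molecule-change transitions
  (alternating or concurrent use); a single clean switch is deliberately
  not multi-statin use, because the rule table treats a bare switch as
  low-confidence evidence only.
* **Permanent discontinuation** — coverage end of the last script
  (date + days supplied; default 30 d when absent, the typical outpatient
  script length) more than `gap_days` (default 180, strict) before study
  end. **Prior discontinuation** — an interior refill gap > `gap_days`
  followed by resumption.
* **Intermittent dosing** — undefined in common rule sets; operationalized
  as the standard claims-data construct, a medication-possession ratio
  (total days supplied / elapsed span incl. last supply) below 0.5 over
  ≥ 3 scripts while still on therapy. Threshold and minimum script count
  are configurable.
* **Low-dose use** — *every* script at or below the molecule's lowest
  marketed daily dose (the exclusive reading: low-dose use as a standing
  state). A separate low-*intensity*-only predicate (all scripts in the
  low band) feeds the low-confidence partial clause; the two differ, e.g.
  atorvastatin 10 mg is the lowest marketed dose but moderate intensity,
  pravastatin 20 mg is low intensity but above its lowest dose.
* **Documented intolerance** — a structured boolean standing in for
  free-text chart notes, which a redistributable schema cannot carry.
* **SAMS** — any configured muscle-symptom code in the lookback.

The rule table maps profiles to five labels with first-match-wins
precedence — high confidence before low, absolute before partial within a
tier — so stronger evidence dominates: (1) ASCVD/high-CV-risk patients
only on non-statin LLT → absolute-high; (2) permanent discontinuation plus
any high-confidence sign (down-titration, low-dose, multi-statin, SAMS,
intermittent dosing, documented note, prior discontinuation) →
absolute-high; (3) the same signs while active → partial-high;
(4) permanent discontinuation with none of its listed exclusion signs →
absolute-low; (5) ASCVD/high-CV-risk patients exclusively on low-intensity
statins with no signs → partial-low; (6) active, non-intermittent patients
with a down-titration or switch → partial-low. The absolute-low exclusion
list is read literally (it omits prior discontinuation and multi-statin
use); in practice those patients are intercepted by clause 2. Never-statin
patients without ASCVD/high-CV-risk tags are not covered by any clause and
fall through to tolerant with an `unclassifiable` flag.

A consequence of the literal reading: a permanently discontinued patient
whose only event is a switch matches no clause and reads tolerant. This
ambiguity is inherent to the rule table and left as is.

## Synthetic cohorts

The generator's defaults define the study conditions. Class mix
(tolerant 0.757, absolute-high 0.064, absolute-low 0.094, partial-high
0.028, partial-low 0.057) follows the reference cohort's label shares with
the tolerant share set to the arithmetic complement. Each planted class is
realized by a trajectory template the detectors map back to it:
discontinued vs active refill chains (28–36-day intervals), down-titration
(atorvastatin 40→20 mg most often — the dominant real-world pattern),
intensity-preserving switches (simvastatin 20/40 → atorvastatin 20),
alternating molecules, lowest-dose or low-intensity regimens, 75–150-day
intermittent spacing, interior >180-day gaps with resumption, documented
notes, SAMS codes, and ezetimibe-only histories. Script counts per history
are deliberately wide (5–24 for active, 5–15 for discontinued patients) so
that prescription volume alone does not separate classes — adherence in
real claims data is strongly heterogeneous, and without this overlap the
calibration task degenerates.

Every high-confidence patient is truly (latently) intolerant; each
low-confidence patient is with probability `latent_si_given_low_conf`
(default 0.5); tolerant patients are not. Latent intolerance scales four
feature signals by fixed rate ratios — myalgia 2.2, cramps 1.9, fibrate
co-prescription 5.0, physician visits 1.3 — over baselines matched to the
reference cohort's tolerant column (1.9%, 2.2%, 1.1%, and a mean of 16
visits over the lookback; the visit ratio is enforced on the *total*
visit-day count, since prescription dates are themselves visits).
Low-confidence patients never receive deterministic sign events: the
latent signal is all the calibration models can use, which is exactly the
population they exist to rescue. Class-independent comorbidity codes
(obesity, hypothyroidism, vitamin D deficiency, CKD, gastritis) and 30
pure-noise codes at 5% complete the feature background.

Incidental myalgia/cramp codes are genuine sign events, so under default
noise the rule engine recovers ~96% of planted labels — e.g. a tolerant
patient with a chance myalgia code is, by the rules' own logic,
partial-high SI. The `noiseless()` scenario zeroes those baselines and
makes recovery exact; tests use it wherever oracle equivalence is
asserted. One practice per patient is simulated (no cross-practice record
linkage), and all randomness flows from a single seed with per-patient
substreams from `(seed, patient_index)`, so output is byte-identical per
seed.

What the generator does **not** emulate: laboratory values (the feature
schema passes them through but nothing emits them), free-text notes,
seasonal prescribing, market-share drift, and correlated comorbidity
structure. Passing tests therefore demonstrate the pipeline's internal
consistency and its ability to recover planted structure — not performance
on real EMR data.

## Features and selection

Per patient and lookback window: presence and count per 3-character ICD
group and per ATC level-4 class; age at index and one-hot gender; total
prescriptions; distinct molecules, ATC classes and LLT molecules; and
distinct active days as the physician-visit proxy (the interchange schema
has no separate visit table). Absences encode as zero; the matrix has no
missing values.

Feature screening ranks columns by mutual information with the
intolerant-vs-tolerant indicator and keeps the top *k* (default 400,
capped at the vocabulary size — synthetic cohorts have ~110 columns, so
the cap binds). Columns with ≤ 20 distinct values are scored with the
plug-in (contingency-table) estimator; continuous columns with the
Kraskov-style k-NN entropy estimator (k = 3, the estimator's customary
default). Estimates are clipped at zero and ties break by column order,
making selection deterministic.

## Calibration

Per task, positives are all high-confidence patients of the class and
negatives a seeded uniform sample of tolerant patients (default 50,000,
capped at availability — the cap binds on desk-scale cohorts). Three
families run with library-default hyperparameters and a fixed seed on
identical stratified 4-fold splits; the F1 winner (ties break by a fixed
family order) is refit on the full set. The decision threshold is swept
over midpoints of consecutive unique out-of-fold scores and set where
|precision − recall| is minimal (lowest threshold on ties); out-of-fold
tuning avoids the optimism of in-sample thresholding, which the underlying
procedure leaves unspecified. Fold-averaged F1/ROC-AUC/PR-AUC are reported
per family. Shapley attributions come from the tree libraries' native
TreeSHAP; the linear family uses permutation importance.

`update_prevalence` moves predicted-intolerant patients from the low- to
the high-confidence row of each class. Tolerant, total and combined SI
counts are invariant; percentages round half-up to one decimal, matching
the usual table formatting.

## Problem sizes and numerical choices

The validation suite runs the full pipeline on 20,000-patient cohorts
(10 seeds × 3 latent fractions for the prevalence-recovery property) and
2,000-patient noiseless cohorts for exact label recovery; these sizes give
per-class counts in the hundreds-to-thousands, large enough for stable
fold metrics while keeping a full run under ~20 s. Degenerate inputs are
errors, not silent defaults: constant targets for MI, single-class folds,
zero training positives, thresholds with no predicted positives are
skipped in the sweep, and contradictory rule inputs (permanent
discontinuation while active) raise.

## Known limitations

* The rule table's silent cases (hypercholesterolemia-only non-statin
  users; discontinued patients with only a switch) default to tolerant —
  flagged, not resolved.
* The precision=recall threshold is tuned at the training prevalence;
  applied to a low-confidence population with a different latent fraction
  it is not guaranteed unbiased. Empirically the recovered share is within
  a few percentage points across latent fractions 0.25–0.75.
* High-confidence patients carry both the latent feature signal *and*
  rule-sign signatures, so the models partly learn signatures the
  low-confidence population lacks; this transfer gap is a faithful
  property of the design, not an implementation artifact.
* Subgroup tags are code-presence only; no risk scoring, no lab-based
  (creatine-kinase) logic, no rechallenge detection beyond prior
  discontinuation, and no cross-practice linkage.
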