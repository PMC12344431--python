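# Methods

## Exposure model

The pipeline treats a dispensing record as evidence of treatment around its
date, not as an exact treatment interval.  Two rules turn dated records into
exposure:

* **Window rule.**  Consecutive dispensings of one drug at most 98 days
  (14 weeks) apart — boundary inclusive — belong to one prescription window;
  a gap of 99+ days starts a new window.  Same-day duplicates collapse to a
  single event.  A window's `n_prescriptions` counts distinct dates; a
  single-dispensing window has `start == end`.
* **Overlap rule.**  Both the citalopram window and the interacting-drug
  window are padded symmetrically by 14 days on each side, and an instance is
  recorded whenever the padded closed intervals intersect.  The overlap
  duration is the inclusive day count of the padded intersection, so two raw
  windows whose facing ends are exactly 28 days apart touch with an overlap
  of one day, and 29 days apart do not overlap.  The "±2 weeks" could also be
  read as one-sided (only after the last prescription); the symmetric reading
  is adopted because dispensing dates lag treatment start as well as lead
  treatment end, and the convention is fixed here rather than inferable from
  data.  Overlap durations are likewise a convention: they are measured on
  the padded intersection, since the padding is precisely the model of actual
  medication exposure.

DDI status is lifetime and binary — at least one instance with any
catalogued drug — with no time-at-risk modelling.  Participants whose
instances all involve single-dispensing drug windows keep their DDI status
but are excluded from overlap-duration estimation (`durations_excluded`),
since a single dispensing gives no within-window duration information.

## Catalogue and name annotation

Interacting drugs carry CYP2C19 PK roles (substrate / inhibitor / inducer), a
pharmacodynamic flag with a four-level severity grade (contraindicated, not
recommended, use with caution, to be considered) and an administration route.
The mildest grade is retained on load but excluded from analysis by default;
PK-only entries have no PD label and therefore severity `none` — they are
kept under the default and topical-exclusion filters and dropped under
contraindicated-only, because the contraindication grades come from the PD
labelling source.  Free-text names are matched case-insensitively as whole
words (tokens delimited by non-letters), so dose strings and formulations
("Omeprazole 20mg capsules") are ignored and near-name collisions
(amitriptyline vs nortriptyline) cannot fire; combination products matching
several synonyms are recorded against every matched entry.  The packaged
catalogue is a deliberately miniature stand-in with one representative per
relevant class (two PPIs, a benzodiazepine, a tricyclic, two contraindicated
PD entries, one topical); real analyses should supply a full regulator-derived
catalogue in the same JSON dialect.

## CYP2C19 phenotyping

Phenotype comes from the unordered pair of star-allele functions: two
no-function alleles → PM; one no-function allele → IM (even against an
increased-function allele); two normal → NM; otherwise with an
increased-function allele → RM_UM (rapid and ultrarapid are analysed as one
group).  Any allele missing from the function table makes the call
indeterminate; indeterminate or absent calls exclude the participant from
phenotype-stratified models only.  The default table covers the common
alleles (*1 normal, *2 and *3 no-function, *17 increased); decreased-function
alleles may be added and map conservatively to IM.

## Statistical stage

* Univariate tests: uncorrected Pearson chi-squared for categoricals
  (multi-level supported) and Welch's unequal-variance *t*-test for
  continuous variables; both choices are fixed, documented policies (the
  equal-variance *t* is available via configuration).  The screen threshold
  is α/m with α = 0.05 and m = 34 by default.  Variables with a single
  observed level are flagged untestable rather than raising.
* Adjusted models: one logistic model per predictor with a shared adjustment
  block, mirroring a per-variable adjusted-OR table rather than one joint
  model.  CIs are Wald on the log-odds scale.  Missing data are handled
  complete-case per model with `n_used` reported; a complete-case count below
  10 rows per model term raises.  Coefficients beyond |15| on the log-odds
  scale are flagged as (quasi-)separation; Newton failures fall back to BFGS
  so the diverging fit is still reported, flagged.
* Duration model: OLS of the longest overlap (days, untransformed by default;
  log1p optionally) on phenotype indicators with NM reference, adjustment
  block minus the citalopram-duration covariate (nearly collinear with the
  outcome), at nominal α = 0.05 as a single pre-specified test.
* Sensitivity: (a) and (b) rebuild the exposure table through the catalogue
  filter (their DDI groups provably nest inside the main group); (c) and (d)
  only edit the adjustment block.  All modes emit structurally identical
  results for diffing.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes — not any real
population.  Covariates are drawn independently from fixed marginals
(female fraction 0.67, age at first citalopram ≈ N(54, 8²), Townsend
N(−1.5, 3²), BMI N(27.5, 5²), four qualification levels, 95% white ethnicity,
smoking 0.45, comorbidity flags with prevalences between 0.02 and 0.60, small
missingness fractions on BMI/Townsend/qualifications).  Intended DDI status
is Bernoulli with logit β₀ + Σβⱼxⱼ, planted βs being ln 2.12 (TRD), ln 2.21
(suicidality), ln 1.91 (heart attack), ln 1.53 (anxiety), ln 1.46
(depression) and 0 elsewhere; β₀ is solved by bracketed root-finding on the
realised covariate draw so the expected prevalence equals the 0.468 target to
within 10⁻³.

Dates are then constructed to make intended status exactly detectable:

* Citalopram: 1–3 windows per participant, 1 + Poisson(5) dispensings per
  window with gaps uniform on 21–84 days (always merging), windows separated
  by 120–400 days (always splitting).
* Intended-DDI participants receive 1 + Poisson(0.96) distinct interacting
  drugs (≈ 1.96 on average), each with a window placed inside a citalopram
  window, occasionally a second window in another citalopram window.  Target
  overlap durations are lognormal (median 68 days, log-sd 1.1, echoing the
  right-skewed overlap durations such records show), shifted by any planted
  phenotype effect and truncated by the host window's span.  A 0.24 fraction
  receives only single-dispensing interacting windows, exercising the
  duration-exclusion path.
* Intended-non-DDI participants receive an interacting drug with probability
  0.35 — but its window ends at least 29 days before the first citalopram
  dispensing, which the padding rule provably cannot bridge.  "No DDI" is
  therefore a non-trivial classification, and truth-vs-detected equality is a
  meaningful end-to-end test.
* Names are emitted with trade-name substitution, case jitter and
  dose/formulation suffixes; unrelated drugs (paracetamol, …) are sprinkled
  in so unmatched-name reporting is exercised.

Diplotypes cover 90% of participants with allele frequencies *1 0.63,
*2 0.20, *17 0.15, *3 0.02 (roughly European CYP2C19), and 0.5% carry an
unknown allele to exercise the indeterminate path.

What the generator does **not** emulate: correlated covariates, indication
bias, disease progression, dose information, calendar effects, and coded
(Read/BNF) rather than free-text drug fields.  Consequently, passing
parameter-recovery tests show the estimator is correct under the assumed
model, not that real-data confounding is handled; the adjusted models here
can only be as good as their covariate set.

A deliberate consequence of the independent-covariate design: each
per-predictor logistic model omits the other planted binary effects, which by
the non-collapsibility of the odds ratio attenuates the conditional log-OR by
roughly 1–3% — small against the sampling error at the tested cohort sizes,
and part of what the coverage simulations measure.  The planted phenotype
effect on overlap duration is likewise attenuated where the host citalopram
window truncates the target duration; the recovery tests therefore assert
sign and significance, not unbiasedness of the shift in days.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of 1,200–20,000 participants and 5–200
replicates, sizes at which every tested property has comfortable statistical
margin.  Root-finding for β₀ uses Brent's method on [−25, 25]; logistic fits
use Newton with a BFGS fallback; all randomness flows from
`numpy.random.default_rng` seeds, and a fixed seed reproduces every table
byte-for-byte.  Dates are day-resolution throughout; intervals are closed and
day counts inclusive.
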