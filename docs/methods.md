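# Methods

This note documents the models and procedures implemented in `htnpathways`,
the defaults chosen where a design was genuinely open, and the limits of
what the synthetic-data tests demonstrate.

## Time and data model

Dates are integer day offsets from a bundle origin (default 2010-01-01);
conversion to ISO-8601 calendar dates happens only at I/O. All intervals
are closed `[start, end]`. A refill record carries an explicit end day
(`start + days_supply − 1`), the CDM-conventional encoding of exposure
duration. The four tables are comma-delimited UTF-8 with header rows;
rows are written in a canonical order so serialization is byte-stable.

The `condition_occurrence` table carries diagnosis categories, procedure
and encounter tokens (`major_surgery`, `pregnancy`, `hospitalization`) and
concomitant-medication dispensing tokens prefixed `rx_`. Anti-HTN
prescriptions live in `drug_exposure` with `drug_class` restricted to the
six-class taxonomy (ACEi, ARB, BB, CCB, DU, OTHER); fixed-dose combination
products must arrive pre-split into ingredient rows — the engine never
parses product names. No vocabulary (ICD/SNOMED/RxNorm) resolution is
attempted; category tokens are the interface.

## Cohort rules

* **Index date**: earliest anti-HTN exposure start `d` with
  `d − history_start ≥ 365`, where history start is the person's earliest
  record in any table (the observation-period-style reading; whether
  "prior clinical history" anchors to observation start or first visit is
  an interpretation, flagged as such).
* **Continuity**: coverage is the day-grid union of exposure intervals
  clipped to `[index, index+1095]` (overlaps not double-counted); the gap
  between adjacent covered intervals is `next.start − prev.end − 1`, so a
  refill the day after exhaustion is a 0-day holiday. Continuous ⇔
  coverage ≥ 875 days and no interior gap > 30 days.
* **Exclusions** are applied in a fixed order (no-prior-history,
  discontinuous, age < 18, major surgery, pregnancy, hCG > 5 strictly,
  missing pre-index BP) and each person is counted under the first failing
  rule, making attrition deterministic.
* **Baseline window** is half-open `[index − w, index)` with `w = 365` by
  default and `w = 183` for the 6-month sensitivity run (6 months has no
  canonical day count; 183 is fixed here). The index-day prescription
  belongs to follow-up. Blood pressure covariates take the last measurement
  strictly before the index date.

## Regimen algebra and change taxonomy

Eras merge refills of the same (ingredient, daily dose) separated by ≤ 30
uncovered days — the same persistence constant as eligibility, on the view
that a single gap tolerance should govern both; it is configurable. The
follow-up window is partitioned at every era boundary into maximal
constant-member regimens. On covered days the member set equals the set of
covering eras exactly; interior uncovered runs ≤ the tolerance carry the
preceding member set forward (a tolerated holiday does not interrupt a
regimen), while longer runs remain as explicit empty-member segments.
Regimens persisting < 30 days are erased and absorbed backwards (the first
regimen is always kept); the filter is idempotent.

Each transition between persisted regimens is classified by fixed
precedence: (R1) identical ingredient sets with dose differences — all
rising → dose increased, all falling → dose reduced; (R2) strict superset →
medication added; (R3) strict subset → medication removed; (R4) same class
multiset, different ingredients → changed within class; (R5) otherwise →
changed to a different class. The precedence resolves the ambiguity of
transitions that are simultaneously describable several ways; mixed dose
moves (one up, one down) fall through to R5 and are logged, and a
cross-class substitution (simultaneous add + remove) is treated as R5 —
a convention, not an assertion about how any particular published table
was assembled. One event is counted per regimen transition, not per
affected drug. Dose comparison uses exact equality of total daily dose in
mg/day per ingredient; no cross-ingredient dose-equivalence conversion is
attempted.

Class-set labels are canonicalized (ACEi < ARB < BB < CCB < DU < OTHER,
joined with `+`); sequences collapse consecutive identical labels (a
dose-only change is invisible at class level) and truncate to five steps.

## Phenotyping

The three lab-based comorbidity rules are ORs over clauses; comparator
strictness follows the operational definitions exactly (TC ≥ 240 inclusive,
HDL < 40 strict, SCr > 1.4 strict, eGFR < 60 strict). The MDRD equation
uses the 4-variable IDMS-traceable coefficient 175 by default; the legacy
186 calibration is available via a parameter. Flags are monotone in window
length by construction (pure disjunctions over in-window records). All
other history flags (diabetes, insomnia, neoplasm, medication classes, …)
are plain category lookups with no lab clause.

## Association analysis

* **2×2 odds ratios**: cross-product ratio `ad/bc`, Wald (Woolf) CI on the
  log scale; a zero cell raises an error unless the 0.5 continuity
  correction is requested.
* **Baseline comparison**: Student's t-test (equal variances) for
  continuous covariates; Pearson χ² without continuity correction for
  binary ones, switching to Fisher's exact test when any expected cell
  is < 5 (the conventional criterion); constant covariates report p = 1.0
  with a warning.
* **Propensity matching**: main-effects logistic model of group membership
  on index year, age, sex, the count of distinct baseline medication
  categories (the implementation of "prescription records"; configurable),
  and the general-history flags. Matching is greedy nearest-neighbour
  without replacement on the logit scale with caliper 0.2 · SD(logit),
  the smaller group driving, candidates processed in descending score
  order and ties broken by a seeded shuffle — the field-standard default,
  stated here because the matching algorithm itself is rarely fully
  specified in published analyses. Covariates that (quasi-)separate the
  propensity model are dropped with a logged warning rather than aborting
  the pipeline.
* **Logistic CIs**: Wald intervals by default; profile-likelihood intervals
  (LR-statistic root finding with offset refits) are available via
  `ci_method="profile"` or `profile_ci`. Point ORs are identical between
  methods; Wald is the default because the pipeline and the repeated-
  simulation suites need thousands of fits and the profile search costs
  an order of magnitude more per term.
* **Stepwise AIC**: candidates are the screened main effects plus all
  pairwise products; search starts from the full candidate model and takes
  the best single add/drop move per step (both directions), enforcing the
  hierarchy principle; non-convergent candidate fits are skipped with a
  warning, and if the full starting model itself is unfittable the search
  restarts from the mains. Because fitting every interaction of every
  Table-1-style covariate is both combinatorially explosive and
  numerically hopeless at a few hundred observations, the pipeline screens
  mains by univariate p < 0.2 and caps the model at 8 terms by default
  (both configurable). Greedy stepwise finds a local AIC minimum; the test
  suite checks agreement with an exhaustive-subset oracle on small
  candidate sets.
* α = 0.05 throughout; no multiplicity correction. ORs and CIs are
  reported to two decimals, percentages to one.

## Synthetic-data generator

The generator's defaults describe the cohort the pipeline is designed for:
mean age 62.5 ± 10.8 years, 55.2% male, initial regimens of 1/2/≥3 drugs
in proportions 63.2/27.5/9.6 (normalized — the printed shares sum to
100.3 due to rounding), an initial class mix dominated by ARB and CCB
(weights proportional to observed monotherapy counts 5/190/36/167/3/1 for
ACEi/ARB/BB/CCB/DU/OTHER), 30-day refills with uniform 0–5-day holidays,
and comorbidity/concomitant-medication prevalences matching a typical
hypertension baseline table. The refill-interval distribution of any real
source system is unknown; 30-day supplies are a stated default, not a
claim of fidelity.

Change events are planted by a logistic model:
`P(changed) = logit⁻¹(intercept + Σ βᵢ·xᵢ)` with defaults
β = 0.02/mmHg on centered diastolic BP, 0.15 on male sex, and 2.3 on
arrhythmia over an intercept of −0.35 (≈ 45–50% changed among eligible,
matching a roughly balanced two-group design). Covariate names may use
`a:b` for products. Each changed person receives 1 + min(Poisson(0.8), 3)
edits at refill-grid boundaries in `[index+90, index+870]`, spaced ≥ 60
days so every planted regimen persists ≥ 30 days; the edit mode is drawn
uniformly from the modes feasible for the current regimen (e.g. removal
requires a combination). Planted eligibility violations are mutually
exclusive per person (one categorical draw), which is what makes exact
attrition-vs-truth comparison meaningful.

Lab values are generated to respect the phenotype thresholds from both
sides: flagged persons cross one clause (or receive the diagnosis),
unflagged persons are clipped safely inside normal ranges, including a
creatinine bounded below both 1.4 mg/dL and the person-specific eGFR-60
threshold. Phenotype labs are pinned at index − 60 days so the 365- and
183-day windows see them identically. The diastolic-BP covariate equals
the recorded index − 7 measurement exactly, so planted logistic effects
are recoverable without measurement-error attenuation.

RNG streams are keyed `[seed, table, person]`, so adding a table or editing
one person never perturbs other draws, and identical configurations yield
byte-identical bundles.

**What the generator does not emulate**: informative missingness, visit
structure and provider behaviour, correlated comorbidities, dose-dependent
adherence, calendar trends in prescribing, multi-institution care, or
free-text anything. Passing tests therefore demonstrate the *correctness
of the pipeline's rules and estimators under the stated data-generating
process*, not robustness to real-world EHR pathologies.

## Problem sizes

The bundled test suite runs the full pipeline at 300–800 persons and the
parameter-recovery checks at 5,000 persons with 500-replicate coverage
simulations; the acceptance script uses the same sizes. These sizes give
binomial/Wald standard errors small enough for 3-SE assertions while
keeping a full run on one CPU in the low minutes.

## Known limitations

* Greedy matching and greedy stepwise selection are order-dependent
  heuristics; both are seeded and deterministic but neither is globally
  optimal.
* The changed/unchanged dichotomy ignores the number and timing of changes
  (no survival modelling); per-person change counts are reported
  descriptively only.
* Complete-record analysis: no imputation of missing labs.
* The continuity requirement selects adherent patients by design; estimates
  generalize only to continuously treated populations.
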