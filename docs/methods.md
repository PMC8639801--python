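# Methods

This note documents the statistical procedure the package implements, the
synthetic data-generating process used to validate it, and the numerical and
design choices made where more than one reasonable option existed.

## Study design

The pipeline mirrors a two-hospital retrospective cohort design: a model is
developed (trained, grid-searched and internally validated) on one site's
CDM-style EHR extract and externally validated, frozen, on a second site's
extract. All tables are day-resolution flat files: PERSON, VISIT,
CONDITION_OCCURRENCE, DRUG_EXPOSURE, LOCATION, plus station-level daily
weather and air-quality records and a station → region map.

### Cohort and outcome

An **index admission** is any inpatient or emergency-room visit of a patient
aged ≥ 65 at admission (computed from year of birth), discharged alive, with
discharge inside the study window and a residence that resolves to a
weather-covered region. Exclusion counts per criterion are logged. Each
qualifying discharge is its own index event; an admission falling inside an
earlier event's outcome window still qualifies (consecutive hospitalizations).

The **outcome** is 1 iff the person has a subsequent emergency-route
admission with admit date in the half-open interval
`(discharge, discharge + 30]` days that is not planned care. Choices pinned
here, with the boundary cases fixed by tests:

* day 0 (re-admission on the discharge date) is a transfer, not a readmission;
* day +30 counts, day +31 does not;
* planned admissions are identified by ICD-10 prefix lists
  (`planned_codes.csv`: chemotherapy Z51.1/Z51.2, organ-transplant
  aftercare Z94.x, rehabilitation Z50) on the diagnoses dated within the
  candidate visit;
* readmissions are sought within the same site's bundle only;
* the earliest qualifying visit supplies the readmission date.

Disease groups (F/I/J/M/other) come from the chapter of the principal —
first-listed, earliest-dated — discharge diagnosis. A subgroup-membership
helper additionally supports multi-membership analyses (a stay with both M
and J diagnoses joins both subgroup cohorts).

### Eras

CONDITION_ERA and DRUG_ERA records collapse occurrences of one concept for
one person into continuous periods using a **30-day persistence gap**
(configurable; the OHDSI convention). The merge test is inclusive
date-distance: a condition occurrence at day 0 and one at day 30 merge at gap
30, day 31 splits; for drug exposures the distance runs from the running
latest end to the next start, so overlapping or contained exposures always
merge. At gap 0, same-day occurrences and touching intervals merge; adjacent
calendar days do not. Equivalence with an O(n²) pairwise-merge oracle is
tested on a thousand random instances.

### Charlson comorbidity index

The Romano adaptation: 17 categories with weights {1, 2, 3, 6}, matched by
ICD-10 prefix from an editable table (`charlson_map.csv`, dots stripped,
longest prefix wins). Each category counts once; three severity pairs are
hierarchical (complicated diabetes over uncomplicated, moderate/severe liver
disease over mild, metastatic solid tumour over any malignancy).

The lookback cutoff is the **index discharge date**. A literal
"all conditions before the end of the readmission interval" cutoff would let
diagnoses recorded during the 30-day outcome window leak into a covariate;
a `charlson_include_outcome_window` switch reproduces that reading for
comparison, but the non-leaking cutoff is the default and is used everywhere
else in the package (era indicators use the same cutoff).

### Weather harmonization and the W-score

Per region, day and element, the harmonized value is the **median across the
region's reporting stations**; remaining missing region-days are filled with
the mean of that element's regional daily medians over the study window and
flagged. An element never observed in a region is a fatal error. If one-sided
imputation leaves `tmin > tmax` on a day, tmin is clipped to tmax (stations
never report an inverted pair; only imputation can create one).

Daily points per element follow two-tier advisory/warning criteria
(`criteria.yaml`), restated at daily resolution:

| element  | trigger      | advisory | warning | persistence | 
|----------|--------------|----------|---------|-------------|
| tmax     | ≥ (heat)     | 33 °C    | 35 °C   | 2 days      |
| tmin     | ≤ (cold)     | −12 °C   | −15 °C  | 2 days      |
| humidity | ≤ (dryness)  | 35 %     | 25 %    | 2 days      |
| rainfall | ≥ (daily mm) | 80 mm    | 150 mm  | 1 day       |
| pm10     | ≥ (µg/m³)    | 150      | 300     | 1 day       |

A tier is met at day *t* only if its threshold test passes on
`persistence_days` consecutive series days ending at *t* (evaluated
retrospectively; days before the series start never qualify). Daily points
are warning = 2, advisory = 1, else 0; both points and thresholds are
configuration. The **W-score** of an index event is the element-wise sum of
daily points over the 7 consecutive days starting at the discharge date
(day 0 included), giving each element a 0–14 range at the default points.
PM2.5, SO₂, NO₂ and O₃ are ingested and exported but never scored — PM2.5 is
heavily missing in source data and collinear with PM10. The scoring engine
accepts observed series (retrospective analysis) or a 7-day forecast series
(the intended deployment at discharge time).

Two readings of "summing the element-specific values over 7 days" exist —
summing raw meteorological values versus summing criterion-based points. The
advisory/warning framing supports the graded-points reading implemented here;
switching to other per-element point values is a config change, not a code
change.

### Features

Column blocks, in fixed order: age (years), male indicator, age-band
indicators (the "60s" band is 65–69 given the inclusion age), season
indicators, length of stay, Charlson index, one binary column per
condition-era group (ICD-10 truncated to 3 characters — a vocabulary-level
concept rollup is not reproducible without vocabulary tables), one per
drug-era ingredient, and, in the `clinical_w` configuration, the five
W-score elements. Era indicators are 1 iff an era of the group starts on or
before the index discharge. Era columns seen in fewer than 10 training events
are dropped (configurable). The training column manifest is persisted;
external matrices are conformed to it exactly (unseen columns dropped,
missing columns zero-filled), so the frozen model always sees the column
space it was trained on.

### Models and evaluation

Families: decision tree, random forest, AdaBoost, gradient boosting
(scikit-learn implementations; the bespoke contribution is the pipeline
around them). Default grids mirror the published hyper-parameter table — DT
(class weighting balanced/none, depth 10, min leaf 10, min split 2, impurity
threshold 10⁻⁷), RF (depth 4/10/17 × features √p/5/20 at 500 trees), ADA
(learning rate 1, 4 estimators), GBM (learning rate 0.005/0.01/0.1 × depth
4/6/17 × 100/1000 trees, min node 2, 25-round early stopping). GBM early
stopping uses a seeded internal 10% validation fraction, since rounds are
specified but no stopping partition.

Procedure: stratified 75/25 train/test split (the development/test fraction
is not dictated by the design; 75/25 is this package's choice), stratified
k-fold CV (k = 10) on the training split over every grid combination, best
mean CV AUROC selected with ties broken to the first point in declared grid
order (logged), refit on the full training split, AUROC on the held-out
split, then external AUROC of the frozen model on the conformed second-site
matrix. Both the CV mean and the held-out AUROC are reported; the held-out
value populates the comparison table. AUROC is computed by the Mann–Whitney
rank formulation (average ranks, ties ½) and is tested against an O(n²)
pair-counting oracle and scikit-learn's implementation.

The covariate summary reports per-column overall / with-outcome /
without-outcome means, sorted by absolute with-versus-without difference.

## The synthetic study generator

The generator emulates the study conditions end to end so that every
downstream stage can be validated against planted truth.

* **Persons.** Ages uniform on 60–99 at window start (so the ≥ 65 filter has
  genuine exclusions), sex balanced, residence uniform over 4 regions.
* **Visits.** 1 + Poisson(0.3) visits per person over a 2017–2018 window,
  admissions uniform up to 80 days before the window end (so every outcome
  and exposure window stays covered); 30% emergency; length of stay
  geometric-like with mean 3 days (0.4 for ER visits), capped at 30; 3%
  in-hospital deaths. A person's spontaneous visits are spaced > 100 days
  apart — far enough that the only admissions ever falling inside a 30-day
  outcome window are the readmissions the generator plants, which makes
  cohort label recovery exact and is verified by test.
* **Diagnoses.** One principal discharge diagnosis per visit drawn from
  chapter pools with mix F 8.7% / I 25.7% / J 28.3% / M 37.3% (patterned on
  a four-chapter elderly case mix); historical comorbidities
  (Poisson(1.2) per person, about half Charlson-mapped) dated strictly
  before the first admission; Poisson(2) drug exposures from a 20-ingredient
  ATC-style pool.
* **Weather.** Per station and day: sinusoidal seasonal cycles with Gaussian
  noise for tmax (mean 18 °C, amplitude 13, sd 3.5) and humidity (62%,
  amplitude 12, sd 10); tmin = tmax − max(1, N(8, 2)); zero-inflated
  exponential rainfall heavier in summer; lognormal PM10 (median ≈ 50 µg/m³,
  log-sd 0.5) with a spring elevation — parameter levels patterned on a
  temperate monsoon metropolitan climate so that heat, heavy-rain and
  fine-dust exceedances occur at realistic, non-degenerate rates. Missing
  reports are injected at 2% by default.
* **Outcome.** For every prospective index event the generator computes the
  TRUE covariates — age, stay, Charlson, disease group and the true W-score
  via the same exposure code the pipeline uses — and draws readmission from
  `logistic(intercept + β·x)`, age centred at 75 so the intercept stays a
  baseline logit. On success an unplanned emergency readmission visit is
  appended at a uniform day in 1..30 after discharge, carrying the index
  stay's principal diagnosis. The default intercept (−2.9) puts marginal
  incidence near 13%, inside the 11–16% band typical of elderly
  disease-group cohorts.
* **Two sites.** The external site is drawn from independent seed streams
  with additive shifts on its generating parameters (default: +1 year mean
  age, −0.5 °C temperatures, +8% PM10) to emulate a neighbouring hospital
  system. Weather, clinical and outcome streams are independent per site, so
  adding persons never perturbs the weather series.

What the generator does **not** emulate: ICD-10 co-occurrence structure,
drug–condition pharmacology, spatial correlation between regions, secular
trends, coding drift between sites, or any real marginal weather–readmission
relationship (the logistic form is an assumption used for recovery testing
only). Passing tests therefore demonstrate that the pipeline recovers signals
of the planted form faithfully — not that such signals exist, or have this
form, in real EHR data.

## Validation scenarios and problem sizes

Two canonical scenarios (`readmitwx.scenarios`) drive the calibration and
recovery studies, at 5000 persons per site:

* **null_signal** — all coefficients zero, incidence 10%: the pipeline must
  score at chance (internal held-out AUROC within 0.5 ± 0.05).
* **strong_w** — strong weather coefficients (0.5, 0.4 and 0.5 log-odds per
  point on PM10, rainfall and heat) over moderate clinical effects (odds
  ratio ≈ 1.5 per Charlson point): the GBM must reach internal AUROC ≥ 0.65
  with W-scores, the W block must add skill over clinical-only in the
  majority of seeds, the injected W elements must out-separate the null
  elements (humidity, cold) in the covariate summary, and the frozen model's
  external AUROC must sit within 0.10 of internal under the default mild
  site shift.

The recovery studies use a deliberately small gradient-boosting
configuration (depth-2, shrinkage 0.05, 300 early-stopped trees, min leaf
20) — at these cohort sizes it recovers nearly all of the planted signal
(the AUROC of the true linear predictor, the Bayes ceiling, is ≈ 0.73–0.74)
while keeping the repeated-seed studies to minutes on one CPU. The full
published grids remain the package defaults.

## Numerical and degenerate-input choices

* Dates are calendar days throughout; no times, no time zones.
* Ties in grid selection go to the first grid point in declared order.
* AUROC on single-class inputs raises rather than returning a default.
* Empty tables are valid everywhere (empty bundle → empty cohort → empty
  matrices); an uncovered exposure window, a missing W-score in `clinical_w`
  mode, an unmapped station and a never-observed region-element are fatal
  with the offending keys named.
* All file outputs are sorted on primary keys with fixed column order and
  ISO-8601 dates, so repeated runs are byte-identical; determinism of the
  full simulate → report chain is asserted at byte level in the tests.

## Known limitations

* Planned-readmission classification uses prefix lists only, not the full
  procedure-category/acuity logic of the CMS hospital-wide readmission
  measure.
* Cross-site readmission detection is out of scope; each site is labelled
  against its own bundle.
* Station-to-region assignment is by explicit map, not geodesic distance;
  sub-daily criteria (e.g. hourly rainfall intensity) are not representable
  in daily series.
* Concept grouping is lexical (3-character ICD-10, ingredient code), not a
  vocabulary rollup.
* Mortality is handled only through the discharged-alive filter; there is no
  post-discharge death censoring of the outcome window.
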