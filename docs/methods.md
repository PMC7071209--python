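# Methods

This note documents the scientific model behind `ppgr-pipeline`: what each
stage computes, the assumptions it makes, the tunable parameters and their
defaults, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the procedure was genuinely open.

## 1. Glycemic index and load

Each food-table entry carries per-100 g composition (carbohydrate, protein,
fat, energy, water, starch, fiber) and a glycemic index with a provenance
tag recording which assignment rule produced it. The assignment hierarchy is
deterministic and ordered: a published GI always wins; foods with less than
5 g carbohydrate/100 g get GI 0; otherwise a close-match GI, a food-subgroup
mean, or an expert default (0, 50, or a nominated value) applies; with no
candidate the GI stays undefined. Undefined-GI foods are legal inputs —
meals containing them flow through matching and are removed only by the
record filter, so their exclusion is counted and reported rather than
silent.

For a dish or meal of items contributing carboᵢ grams of carbohydrate,

  gi = Σ giᵢ·carboᵢ / Σ carboᵢ  gl = (1/100) Σ giᵢ·carboᵢ

so `gl = gi · carbo_total / 100` holds as an algebraic identity, which the
test-suite asserts to 1e-9. "carboᵢ" is interpreted as grams of carbohydrate
in the consumed portion, not a dimensionless mass fraction: only that
reading yields conventional GL units (80 g of white bread ≈ GL 29) and
makes gl commensurable with the carbohydrate regressor. An
all-zero-carbohydrate dish is assigned GI 0 by convention, consistent with
the zero-carb assignment rule. GI is validated on [0, 150] (published
values exceed 100 for a few foods); meal-level GI is always recomputed from
the items rather than read from a stored dish value.

## 2. Record linkage and exclusion rules

The paper protocol's start time is treated as the authoritative meal start;
the diary contributes the food content. Matching is greedy one-to-one by
ascending absolute time difference with a 60-min cap (the cap prevents
pathological cross-day matches; protocol entries with no diary record inside
it are dropped and counted).

Glucose is linearly interpolated on the trace; queries within ±2.5 min of
the trace edges clamp to the edge sample (protocol times fall between the
nominal 5-min samples), and interpolation across a sampling gap wider than
20 min is refused. Exclusion rules are evaluated on interpolated values, in
a fixed order with first-match-wins labeling, so each excluded meal carries
exactly one reason and per-rule counts partition the exclusions:

1. **late_report** — BG(t) − BG(t−60 min) > 1.0 mmol/L;
2. **falling_edge** — BG(t) ≥ BG(t+30) + 0.5 and BG(t) ≤ BG(t−30) − 0.5 mmol/L;
3. **prior_meal** — another matched meal start strictly inside (t−60, t);
4. **subsequent_meal** — another matched meal start strictly inside (t, t+60).

Rules 3–4 consider all protocol-matched starts of the same patient,
including meals themselves excluded. A meal whose required glucose values
fall in a sensor gap or outside the span is excluded as `cgm_unavailable`
(the source procedure is silent on gaps; dropping with a counted reason is
the conservative choice). All four thresholds are configurable.

## 3. PPGR outcomes and filters

Eight outcomes per meal: BG0 and BG60 (interpolated), BGMax over
[0, 180 min] (raw samples plus interpolated window edges), BGRise =
BGMax − BG0, trapezoidal AUC60/AUC120, and incremental iAUC60/iAUC120 above
the BG0 baseline. iAUC uses the positive-increment convention of standard
GI methodology — segments below baseline contribute nothing — with
baseline-crossing points inserted exactly, so the integral is exact for the
piecewise-linear interpolant (verified against an independent
root-finding/integration oracle to 1e-9). Time is handled in minutes;
areas are reported in mmol/L·h.

Patient-level misreporting: a diary consisting entirely of single-item
meals, or containing more than five meals whose every portion is a multiple
of 100 g, flags the patient and removes all their records. Record-level
filters then remove meals containing a GI-undefined item, and meals with
more than 40 g carbohydrate whose mean incremental rate iAUC120/2 h is
below 0.3 mmol/L/h — the only reading of "0.3 mmol/L/h" with consistent
units; an implausibly small response to a large carbohydrate load indicates
a mis-timed or mis-recorded meal.

## 4. Feature assembly

One row per kept meal: the nine meal-composition regressors (gi, gl, carbo,
prot, fat, kcal, water, starch, fiber), pre-meal glucose BG0 as a context
feature, and the patient profile. Missing patient values (the only
missingness in the data) are imputed by the column mean within the
patient's group (GDM or control); imputed ordinal values are rounded to the
nearest declared level so they remain encodable. Ordinal questionnaire
items (0/1/2, assessed before and during pregnancy) are dummy-encoded with
`variable_value` names (e.g. `fruits1_2`); binary history items pass
through as 0/1 (equivalent to dummy-encoding up to the reference level).
The roster is declared in a YAML spec (name, block, type, levels) rather
than hard-coded; the bundled fixture spec has 64 declared variables
expanding to 142 encoded features — counts are configurable, not fixed.

The "without GI/GL" arm drops gi and gl — and, when polynomial meal
features are active, their squares and cross-products — leaving everything
else byte-identical.

## 5. Models

**Stepwise track** (descriptive, full record set): forward-only greedy
selection maximizing R², computed via Gram matrices so the trace is
invariant under row permutation; ties in R² gain break by column order for
reproducibility. The stopping rule is a partial-F entry test at
α_enter = 0.05 (configurable) — the conventional criterion of classical
statistics packages; a finite final model implies some such rule even when
only R² is reported as the objective. No removal step is implemented.

**Regularized track** (predictive, held-out patients): a grouped 70/30
patient split (patients shuffled by seed, accumulated until the training
side holds ≈70 % of rows), then per candidate hyperparameter a grouped
k-fold CV (default k = 10; patients assigned to the currently smallest fold
for balance). Inside every training fold — never on validation data — the
Spearman prefilter retains features with |r| > 0.1 against the outcome and
columns are normalized by subtracting the mean and dividing by the
centered-column ℓ₂ norm; the stored constants are reapplied verbatim at
validation/test time. Estimators are scikit-learn's
OrthogonalMatchingPursuit, LassoLars, Lasso, Ridge and ElasticNet; grids
default to support size 1–30 for OMP and a 20-point log-spaced alpha grid
1e-4…10 (× l1-ratio {0.1, 0.5, 0.9} for elastic-net) — OMP's natural
hyperparameter is its support size, so "alpha" grid search maps to a
support-size grid there. The grid point with the largest mean validation
coefficient of determination wins (negative values allowed, with a
warning), and the model refits on the full training split. Fitted models
serialize to JSON text with their normalization constants, making the
no-leakage property directly testable: permuting held-out patients'
outcomes leaves the serialized model byte-identical.

Evaluation reports Pearson R between predicted and observed responses, MAE
and r² on the held-out patients, plus (for iAUC120) the fraction of
predictions off by more than 1.0 mmol/L·h. Zero-variance predictions
report R as NaN rather than a fabricated value.

## 6. The synthetic-data generator

The generator is the test harness: the source procedure includes no
generative model, so this one is designed to exercise every pipeline rule
under known ground truth while staying physiologically plausible.

**Cohort.** 44 GDM + 16 control patients (the study's ≈2.6:1 ratio at the
60-patient scale), 6 monitored days, 5 intakes/day (3 mains + 2 snacks, the
frequent-small-meals pattern of GDM dietary advice) — ~1800 generated
meals, ~1450 surviving all filters. Profiles follow the bundled feature
spec with directional GDM shifts (higher BMI, OGTT glucose, HbA1c,
triglycerides) that are qualitative only, not calibrated to any cohort
table; 4 % missingness in the numeric block exercises the imputer.

**Glucose trace.** Per patient: basal level (GDM 4.9, control
4.5 ± 0.35 mmol/L) + a circadian sinusoid (amplitude 0.5, random phase) + a
slow Ornstein–Uhlenbeck drift (sd 0.3, 3-h correlation time), plus per-meal
responses and AR(1) sensor noise (sd 0.1 mmol/L, lag-5-min correlation 0.7
— smooth traces, so the interpolation-based rules face realistic input),
clipped to [2, 25] mmol/L. The meal response is a gamma-shaped kernel
(t/τ)^a·exp(a(1−t/τ)) with peak at τ = 45 min and shape a = 4, normalized
to unit iAUC120, so a meal's planted amplitude *is* its noiseless iAUC120;
the extractor recovers it within a 0.02 mmol/L·h discretization tolerance.

**Planted signal.** amplitude = β₀ + β_carbo·carbo + β_gl·gl + β_bg0·BG0 +
u_patient + ε, clipped at zero, with defaults β = {carbo 0.012, gl 0.045,
bg0 −0.35}, β₀ = 3.4 mmol/L·h, patient effect sd 0.3 and meal noise sd
1.15. Two calibrations fixed these values before the acceptance
measurements were run:

* *Prediction ceiling.* `theoretical_r` computes corr(signal, outcome)
  under the generative model by Monte Carlo over the meal/covariate
  distributions (a fixed internal stream — it is a numerical expectation,
  not a per-run simulation), including amplitude clipping and a closed-form
  propagation of the AR(1) sensor noise through the trapezoid/baseline
  weights of the iAUC estimator. The noise sd is set so this ceiling is
  ≈ 0.6, the regime of realistic free-living PPGR prediction.
* *Identifiability.* Because gl ≡ gi·carbo/100 exactly, carbo has almost no
  unique linear variation given gi and gl (residual sd ≈ 1.3 g against a
  marginal 23 g), so no linear selector can reliably pick `carbo` itself
  out of the collinear block at this noise level — its best-case partial t
  is < 2 regardless of β. The default scenario therefore carries the
  carbohydrate-axis signal mainly on gl, and "signal recovery" is assessed
  on the identifiable components: gl and BG0 selected with correct signs,
  plus the fitted model's implied marginal carbohydrate slope (positive
  whichever collinear carrier the selector picks).

**Reporting errors.** With configurable probabilities per meal: the
recorded start time (protocol *and* diary — app entries are made late too)
is delayed 40–55 min onto the rising peak (late-report exclusions) or
τ+30–45 min onto the falling edge; an unplanned snack is inserted 25–55 min
before a meal in both record streams (prior/subsequent-meal exclusions);
the diary record is deleted (unmatched protocol entries). A configurable
fraction of patients emit single-item or 100 g-rounded diaries. Default
rates (4.5 %, 1.5 %, 3 %, 3 %, 10 % misreporters) echo the proportions such
cohorts report. Detection is intentionally imperfect where the rule's
physics make it so: a late report is caught only when the excursion crosses
the 1.0 mmol/L threshold (≈88 % of injections at the default amplitude
distribution), and the falling-edge margins are crossed by ≈60 % of
falling injections — small responses genuinely cannot be distinguished
from honest reports, so realized exclusion fractions sit slightly below
injected rates.

**What passing tests do not show.** The generator's outcome model is
linear by construction; real PPGR has nonlinearities, meal-context and
gut-microbiome effects the linear tracks cannot capture. Covariate shifts
between groups are directional, not calibrated; food portions, not intake
timing, carry the signal; and patient features other than the planted three
are pure noise, so feature-selection behavior on real data — where many
weak patient-level signals exist — may differ. Absolute MAE and
error-fraction values depend on the scenario's amplitude scale and are not
comparable to any clinical cohort.

## 7. Numerical choices and degenerate inputs

Interpolation is linear everywhere; 20-min maximum bridgeable gap; ±2.5-min
edge tolerance. AUC integration inserts interpolated window endpoints and
exact baseline crossings. Stepwise ties break by column order; grouped
splits and folds are deterministic given a seed; zero-norm columns are
dropped from normalization with a warning; an empty hyperparameter grid, a
single patient (unsplittable), fewer patients than folds, a constant
outcome, and rank-deficient stepwise candidates are all explicit errors or
warned skips rather than silent misbehavior. The `simulate` CLI stage and
`write_cohort` emit plain CSV; re-running any stage with an unchanged
config reproduces byte-identical artifacts, and a stage-wise run equals an
`all` run.

## 8. Problem sizes used by the test-suite

The acceptance checks run the full pipeline at the default scenario
(60 patients, ~1800 meals) for 50 seeds for signal recovery and 20 seeds
per arm-sensitivity scenario; injected-error recovery uses an 18-patient /
540-meal cohort; the AUC oracle uses 200 random traces; grouped-split
leakage checks use 20 seeds. These sizes give binomial/Monte-Carlo margins
comfortably tighter than the asserted tolerances while keeping the whole
suite in a few minutes on one CPU.
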