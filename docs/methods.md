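# Methods

This note documents the models implemented in `dietfrail`, the defaults
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the underlying methodology leaves the
design open.

## Deficit-accumulation indices

An index is a ratio: the sum of item deficit scores over the number of
items assessed. Items are declarative rules over one source column each —
`threshold` (deficit below/above a cut-off, optionally sex-specific),
`band` (deficit outside an inclusive healthy interval), `categories`
(explicit mapping, supporting graded items such as 0 / 0.5 / 1 for
self-rated health), and `interval` (graded scores over ordered
breakpoints). Graded items are supported because the deficit-accumulation
literature uses them, although the packaged defaults are binary except for
self-rated health.

**Item rosters and cut-offs.** The packaged Nutrition Index has the
canonical 31-item roster (18 nutrient intakes, 3 anthropometrics, 10
nutrition-related blood tests) and the frailty index the 36-item roster of
self-report, vital-sign and laboratory items. The cut-offs themselves are
editable YAML defaults chosen once from conventional clinical reference
ranges and DRI-style intake thresholds (e.g. hemoglobin < 13/12 g/dL by
sex, serum albumin < 3.5 g/dL, fasting glucose outside 70–126 mg/dL,
protein < 0.8 g/kg/day, sodium intake > 2300 mg/day). Real analyses can
and should swap in their protocol's thresholds; the scoring engine never
hard-codes any.

**Missing data.** The denominator is the number of items assessed. When
fewer than `min_nonmissing_fraction` (default 0.8) of the expected items
are assessed, the index is reported missing rather than extrapolated. No
imputation is performed.

**Design choices.**

* "Body weight change in the past year" is scored symmetrically (|change| >
  4.5 kg is a deficit): both unintentional loss and rapid gain indicate
  nutritional perturbation, and a one-sided rule would silently treat gain
  as healthy.
* BMI appears both as an NI item and (categorised) as a regression
  covariate; the two uses are kept, as in the source analyses.
* The frailty and nutrition item sets are disjoint by construction —
  `validate_frailty_independence` reports any shared source column — so the
  frailty index never encodes nutritional status. Where a lab could serve
  either index (e.g. glucose vs diagnosed diabetes), the NI takes the lab
  and the FI the self-reported diagnosis.

## E-DII

Each parameter's daily amount is converted to a density per 1000 kcal,
standardised against the reference mean and SD, and mapped to a centred
percentile `2Φ(z) − 1 ∈ (−1, 1)`; the total is the effect-score-weighted
sum. The normal-CDF percentile is the documented construction of the
centred-percentile step. Consequences tested: the total is bounded by
Σ|effect score|, monotone in each parameter's density with the sign of its
effect score, and invariant to rescaling all amounts and energy together.

The packaged reference table (`edii_reference_synthetic.csv`) is
**synthetic**: per-1000-kcal means and SDs are plausible values chosen
once, and effect scores carry literature-consistent signs. The licensed
global reference table must be supplied for substantive analyses; the
table's SHA-256 checksum is exposed so runs record which table scored them.
Missing parameters are skipped (the score runs over parameters available),
with a `reference_mean` option that scores a missing density as zero
contribution instead; no capping is applied to alcohol or caffeine.

## HEI-2015

The 13 published component standards ship as config defaults. Scoring is
piecewise-linear between the two standards of each component and flat
outside. Density bases: cup/oz equivalents per 1000 kcal; % of energy for
added sugars (4 kcal/g) and saturated fat (9 kcal/g); sodium in grams per
1000 kcal; and the (MUFA+PUFA)/SFA ratio. Limit behaviour of the ratio is
defined and tested: SFA = 0 with unsaturated fat present scores the
maximum; a 0/0 ratio scores zero. Missing component amounts propagate to a
missing total by default; an explicit `zero_intake` flag treats them as
zero consumption instead.

## MDS and DASH

MDS medians are computed on the analytic sample being scored, unweighted by
default (a weighted median is available); they are serialisable so scores
are reproducible across runs. Tie rule: favourable components award at
value ≥ median, unfavourable at value < median. The alcohol band is
inclusive at both ends (14–28 g/day women, 28–70 g/day men), since the
printed ranges carry no bracket convention. Potatoes are excluded from the
vegetable group upstream, and the fish group is shrimp, clams and fish.

DASH goal and control-diet values for the nine nutrients are config
defaults transcribed from the published nutrient-based DASH index and
control-diet composition; the intermediate threshold is the midpoint of
goal and control. Protein, total fat and saturated fat are scored as % of
energy; fiber, magnesium, calcium, potassium, cholesterol and sodium per
1000 kcal.

## Synthetic cohort

The generator emulates the structural features the pipeline must handle:

* ages uniform on 20–85, roughly balanced sex, categorical covariates with
  fixed plausible frequencies, positive lognormal sampling weights;
* energy lognormal with log-mean 7.594 and log-SD 0.437 (mean ≈ 2180 kcal,
  SD ≈ 1000 kcal — right-skewed adult intake);
* each nutrient/food-group amount = slope × energy/1000 + Gaussian noise
  (CV 0.35), truncated at zero, so per-1000-kcal densities exist and vary;
  alcohol is zero-inflated (40% drinkers, lognormal amounts) and not
  energy-coupled;
* lab/exam values are drawn by inverting each deficit rule: a Bernoulli
  draw decides whether the item fires (default prevalence 0.20 for NI
  lab/exam items), then a value is drawn uniformly inside the corresponding
  healthy or deficit region, honouring sex-specific cut-offs;
* frailty-item prevalences rise with age on the logit scale (slope
  0.04/year around a base of 0.075 at age 50), giving a frailty index
  concentrated near 0.10 with an age gradient;
* survival: constant baseline hazard (default 0.01/person-year) times
  `exp(β_FI · FI/0.1 + β_diet · score)`, with uniform administrative
  censoring on [3, 8] years. The exponential baseline keeps a closed-form
  null for testing; Cox estimation is baseline-agnostic, so nothing is lost
  for the association stage. One designated "driver" diet score enters the
  hazard at a time, which keeps parameter-recovery experiments identifiable.

What the generator does **not** emulate: real dietary correlation
structure beyond the shared energy factor, survey design (strata/PSU),
score–score joint distributions, or any cohort's descriptive statistics.
Passing tests therefore demonstrate the correctness and calibration of the
scoring and regression machinery under a known truth — not that any
substantive epidemiological estimate transfers to real data.

## Association stage

* **Unit scales.** Coefficients are reported per 0.1 point for the deficit
  indices, per 10 points for HEI-2015, and per point for E-DII, MDS and
  DASH.
* **Polynomial selection.** For each exposure the linear model is fitted,
  then the squared term added, then the cubic. Terms are mean-centred
  before powering (after unit scaling) to tame collinearity; centring
  changes lower-order coefficients' interpretation but not the top term's
  test. The reported model is the highest-degree one whose highest-order
  term has two-tailed p < 0.05, falling back to linear. Under a linear
  truth the quadratic model is selected at ≈ α·(1−α) ≈ 4.75%, verified by
  simulation.
* **Weights.** Survey weights enter OLS as WLS with HC1 robust variance and
  Cox as case weights with robust sandwich variance. Six-year weights are
  the 2-year weights divided by the number of pooled cycles (default 3).
  Design-based (strata/PSU) variance estimation is out of scope.
* **Cox details.** Follow-up is right-censored at the 3- or 8-year window
  before fitting (events after the window become censored at the cap). Ties
  use lifelines' Efron approximation. Models adjust for the basic
  covariates plus the continuous frailty index by default; the Nutrition
  Index can be added (`include_ni`). Energy (kcal) is added automatically
  exactly when MDS is the exposure and the NI is not in the model, because
  every other score is energy-adjusted internally.
* **Complete cases.** Each model drops rows with missing values among its
  own columns only.
* **Diagnostics.** Pairwise two-score models report the VIF between the
  exposures, `1/(1 − r²)`, with a warning above 10. Rank-deficient designs
  raise an error naming constant/collinear columns rather than silently
  pseudo-inverting.
* **Interactions.** `interaction_tests` adds the full product of the score
  with the chosen moderators (age, sex; plus frailty for mortality)
  together with all lower-order products, and reports the Wald p of the
  single highest-order term. Moderators are mean-centred.

## Problem sizes used in validation

The test suite validates parameter recovery with 50 replicate cohorts of
n = 20,000 at a true hazard ratio of 1.15 per 0.1 NI point (95% CI coverage
≥ 90%, and nominal coverage at the null), selection-rule calibration with
1,000 simulations of n = 400, and median-split balance on an n = 10,000
cohort. Oracle-equivalence checks (brute-force deficit recounts, textbook
Pearson/VIF/weighted-median/E-DII formulas) run on 1,000 random records.

## Known limitations

* The NI/FI cut-offs and the E-DII reference table are defaults for
  pipeline validation, not a clinical standard; substantive analyses must
  configure them.
* Variance estimation ignores survey design (weights only).
* No multiple imputation; missing data are handled by complete-case
  analysis per model and by the deficit-index completeness rule.
* The synthetic cohort's frailty index is independent of diet given age, so
  diet–frailty regressions on simulated data estimate a true null; only the
  mortality pathway carries a built-in diet effect.
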