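# dietfrail

Diet-quality scoring, deficit-accumulation indices, and their association
with frailty and mortality, for NHANES-style cross-sectional cohorts with
mortality follow-up.

`dietfrail` is aimed at nutritional-epidemiology analysts who want a tested,
configurable implementation of five dietary scoring procedures and a
deficit-accumulation frailty index, plus the regression stage that relates
them to health outcomes — all runnable end-to-end on a built-in synthetic
cohort, so no restricted data download is required to validate the pipeline.

## What it computes

**Deficit-accumulation indices.** An index over a set of items, each mapping
a raw measurement to a deficit score in [0, 1], reported as

```
index = (sum of item deficit scores) / (number of items assessed)  ∈ [0, 1]
```

Two instances ship as editable YAML configs:

* **Nutrition Index (NI)**, 31 items: 18 nutrient intakes, 3 anthropometric
  measures, 10 nutrition-related blood tests; higher = worse nutritional
  status. It splits into an 18-item *NI-nutrient* and a 13-item
  *NI-lab/exam* sub-index.
* **Frailty index (FI)**, 36 items: self-report health and function, vital
  signs, laboratory tests; higher = frailer. No FI item shares a source
  measurement with the NI (checked by `validate_frailty_independence`).

**E-DII** (energy-density Dietary Inflammatory Index). Each dietary
parameter is expressed per 1000 kcal, standardised against a reference
distribution and converted to a centred percentile via the normal CDF:

```
z = (density − μ_ref) / σ_ref,   E-DII = Σ_p (2Φ(z_p) − 1) · w_p
```

where `w_p` is the parameter's literature-derived inflammatory effect
score. Higher = more pro-inflammatory. The packaged reference table is
synthetic (the licensed global intake database is not public); supply the
licensed table for real analyses.

**HEI-2015** (0–100): 13 components scored by piecewise-linear
interpolation of per-1000-kcal densities, % of energy, or the
(MUFA+PUFA)/SFA ratio between published standards.

**MDS** (0–10): one point per favourable food group at/above the cohort
median, per unfavourable group below it, and for alcohol inside the
sex-specific moderate band (14–28 g/day women, 28–70 g/day men).

**DASH** (0–9): nine energy-adjusted nutrient targets scored 1 at the goal,
0.5 at the midpoint between the goal and the DASH-trial control diet, else 0.

**Association stage** (statsmodels-style Model → Results):

* `FrailtyModel(data, score).fit()` — OLS of the frailty index on a
  unit-scaled score, testing linear, squared and cubic terms and reporting
  the highest-order model whose top term is significant, with 95% CIs and
  standardized betas (`b · SD(score)/SD(FI)`).
* `MortalityModel(data, score, window=3 or 8).fit()` — Cox proportional
  hazards on follow-up right-censored at the analysis window, adjusted for
  the basic covariates and the continuous frailty index, reporting hazard
  ratios per score unit (per 0.1 point for deficit indices, per 10 points
  for HEI-2015, per point otherwise).
* `score_correlations`, `pairwise_score_models` (with VIF diagnostics) and
  `interaction_tests` (score × age × sex, plus frailty for mortality).

**Synthetic cohorts.** `simulate_study(SimulationConfig(...))` generates an
NHANES-like cohort (lognormal energy, energy-coupled nutrients, lab/exam
values firing each deficit at a configured prevalence, age-graded frailty
items) and exponential survival times whose log-hazard is linear in the
frailty index and one designated diet score, censored uniformly between 3
and 8 years.

## Worked example

```python
import numpy as np
import dietfrail as dfp

cfg = dfp.SimulationConfig(
    n=10_000, seed=1,
    diet_beta=np.log(1.15),      # true HR 1.15 per 0.1 NI point
    baseline_hazard=0.005,
)
cohort = dfp.simulate_study(cfg)     # cohort + FI + NI + follow-up
scored = dfp.score_all(cohort)       # adds E-DII, HEI-2015, MDS, DASH

res = dfp.MortalityModel(scored, "nutrition_index", window=8, degree_max=1).fit()
print(res.summary())
```

prints

```
Cox PH: window=8.0y, exposure=['nutrition_index'] (unit scale {'nutrition_index': 0.1}), selected degree=1, n=10000, events=523
                    coef       hr  hr_ci_low  hr_ci_high       pvalue
term
nutrition_index  0.10513  1.11086    1.05096     1.17417  0.000201342
```

The estimated hazard ratio per 0.1 NI point is 1.11 (95% CI 1.05–1.17),
covering the generating value of 1.15: each 0.1-point rise in accumulated
nutritional deficits multiplies the 8-year mortality hazard by ~1.1 in this
synthetic cohort, independent of frailty. Shortening the window
(`window=3`, 279 events) widens the CI to 0.98–1.15 — the same attenuation
pattern short-horizon analyses show.

The same pipeline runs from a shell:

```
dietfrail simulate --n 10000 --seed 1 --out cohort.csv
dietfrail score --cohort cohort.csv --out scored.csv
dietfrail associate --scored scored.csv --window 8 --out results/assoc
```

## Layout

```
src/dietfrail/
  cohort.py       data model, delimited I/O, exclusions, weight pooling
  deficits.py     deficit-accumulation engine (NI, FI) + YAML configs
  edii.py         E-DII with (synthetic) reference table
  hei.py          HEI-2015 component scoring
  patterns.py     MDS and DASH
  scoring.py      one-call scoring of all eight score columns
  simulate.py     synthetic cohort + survival generator
  association.py  FrailtyModel / MortalityModel, correlations, VIF, interactions
  examples.py     boundary diets/participants used as worked examples
  cli.py          `dietfrail simulate|score|associate`
docs/methods.md   modelling assumptions, defaults, limitations
```
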