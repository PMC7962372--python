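"""Synthetic NHANES-like cohort generator with known ground truth.

The generator emulates the structural features the downstream stages
exercise, without attempting to match any real survey's joint
distributions:

* adults aged 20-85, roughly sex-balanced, with categorical covariates;
* right-skewed (lognormal) total energy intake;
* nutrient and food-group amounts linearly coupled to energy with additive
  noise truncated at zero, so per-1000-kcal densities are well defined;
* laboratory / exam / self-report values drawn so each deficit item fires
  with a configured prevalence (frailty-item prevalences rise with age on
  the logit scale, concentrating the frailty index near 0.10);
* survival times from a constant (exponential) baseline hazard whose
  log-hazard is linear in the frailty index (per 0.1 unit) and in one
  designated diet score, with administrative censoring drawn uniformly
  between 3 and 8 years.

The constant baseline keeps closed-form null distributions available for
testing, and Cox estimation is agnostic to the baseline anyway.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd

from dietfrail.cohort import BMI_CATEGORIES, EDUCATION_LEVELS, MARITAL_LEVELS, RACES, SMOKING_LEVELS
from dietfrail.deficits import DeficitDefinitionSet, DeficitItem, score_deficit_index
from dietfrail.errors import DomainError

#: mean nutrient amount per 1000 kcal of energy (canonical units/day)
DEFAULT_NUTRIENT_SLOPES = {
    "nut_protein_g": 38.0,
    "nut_carbohydrate_g": 125.0,
    "nut_total_fat_g": 38.0,
    "nut_saturated_fat_g": 12.5,
    "nut_mufa_g": 13.0,
    "nut_pufa_g": 8.5,
    "nut_omega3_g": 0.8,
    "nut_omega6_g": 7.0,
    "nut_cholesterol_mg": 135.0,
    "nut_fiber_g": 8.0,
    "nut_vitamin_a_mcg": 290.0,
    "nut_vitamin_c_mg": 40.0,
    "nut_vitamin_b1_mg": 0.75,
    "nut_vitamin_b2_mg": 1.0,
    "nut_vitamin_b3_mg": 11.0,
    "nut_vitamin_b6_mg": 0.9,
    "nut_vitamin_b12_mcg": 2.4,
    "nut_vitamin_d_mcg": 2.1,
    "nut_vitamin_e_mg": 3.8,
    "nut_folate_mcg": 190.0,
    "nut_beta_carotene_mcg": 1100.0,
    "nut_iron_mg": 6.5,
    "nut_magnesium_mg": 130.0,
    "nut_selenium_mcg": 50.0,
    "nut_zinc_mg": 5.3,
    "nut_phosphorus_mg": 620.0,
    "nut_copper_mg": 0.55,
    "nut_sodium_mg": 1650.0,
    "nut_calcium_mg": 440.0,
    "nut_potassium_mg": 1250.0,
    "nut_caffeine_mg": 80.0,
    "nut_fish_oil_g": 0.12,
    "nut_added_sugar_g": 33.0,
    # food-pattern equivalents (cup / oz eq per 1000 kcal)
    "fpe_total_fruits_cup": 0.5,
    "fpe_whole_fruits_cup": 0.25,
    "fpe_total_vegetables_cup": 0.8,
    "fpe_greens_beans_cup": 0.12,
    "fpe_whole_grains_oz": 0.45,
    "fpe_dairy_cup": 0.9,
    "fpe_total_protein_oz": 3.2,
    "fpe_seafood_plant_protein_oz": 0.35,
    "fpe_refined_grains_oz": 3.2,
    # Mediterranean food groups (g per 1000 kcal)
    "mds_non_refined_cereals_g": 30.0,
    "mds_legumes_g": 20.0,
    "mds_fruits_nuts_g": 120.0,
    "mds_vegetables_g": 130.0,
    "mds_fish_g": 25.0,
    "mds_red_meat_g": 50.0,
    "mds_poultry_g": 45.0,
    "mds_dairy_g": 150.0,
}

#: default prevalence at which each configured lab/exam/self-report deficit
#: fires. The frailty-item base rate of 0.075 at age 50, combined with the
#: age gradient over a uniform 20-85 age range, gives a marginal item
#: prevalence near 0.10, concentrating the frailty index around 0.10.
DEFAULT_LABEXAM_PREVALENCE = 0.20
DEFAULT_FRAILTY_PREVALENCE = 0.075


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort and its survival structure."""

    n: int = 1000
    seed: int | None = None
    # energy: lognormal chosen to give mean ~2180 kcal, SD ~1000 kcal
    energy_log_mean: float = 7.5936
    energy_log_sd: float = 0.4374
    nutrient_energy_slopes: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_NUTRIENT_SLOPES)
    )
    nutrient_noise_cv: float = 0.35
    deficit_prevalences: Mapping[str, float] = dataclasses.field(default_factory=dict)
    age_logit_slope: float = 0.04  # frailty-item prevalence gradient per year of age
    # survival structure
    frailty_beta: float = float(np.log(1.3))  # log-hazard per 0.1 frailty-index unit
    diet_beta: float = 0.0  # log-hazard per unit of the designated diet score
    driver_score: str = "nutrition_index"
    driver_unit_scale: float = 0.1  # designated score divided by this before the hazard
    baseline_hazard: float = 0.01  # events per person-year
    censor_years: float = 8.0
    followup_min_years: float = 3.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("n must be >= 1")
        if self.energy_log_sd < 0 or self.nutrient_noise_cv < 0:
            raise DomainError("scale parameters must be >= 0")
        for k, p in dict(self.deficit_prevalences).items():
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"prevalence for {k!r} must be in [0, 1], got {p}")
        if self.censor_years <= 0 or not 0 < self.followup_min_years <= self.censor_years:
            raise DomainError("need 0 < followup_min_years <= censor_years")


def _sample_rule_value(
    rng: np.random.Generator, item: DeficitItem, deficit: np.ndarray, sex: np.ndarray
) -> np.ndarray:
    """Draw raw values that fire (or not) ``item``'s deficit rule per row.

    Supports threshold, band, and categories rules — the ones the packaged
    configs use. Interval rules are scoring-only and not invertible here.
    """
    n = deficit.shape[0]
    rule = item.rule
    rtype = rule["type"]
    if rtype == "threshold":
        cut = rule["cutoff"]
        if isinstance(cut, Mapping):
            cuts = np.where(sex == "male", float(cut["male"]), float(cut["female"]))
        else:
            cuts = np.full(n, float(cut))
        frac = rng.uniform(0.05, 0.45, size=n)
        below = cuts * (1.0 - frac)
        above = cuts * (1.0 + frac)
        if np.any(cuts <= 0):  # additive offsets when the cut-off is not positive
            below = np.where(cuts <= 0, cuts - 1.0 - frac, below)
            above = np.where(cuts <= 0, cuts + 1.0 + frac, above)
        if rule["direction"] == "low":
            return np.where(deficit, below, above)
        return np.where(deficit, above, below)
    if rtype == "band":
        lo, hi = float(rule["low"]), float(rule["high"])
        width = hi - lo
        healthy = rng.uniform(lo + 0.05 * width, hi - 0.05 * width, size=n)
        side_high = rng.random(n) < 0.5
        out_low = lo - rng.uniform(0.05, 0.4, size=n) * max(abs(lo), width)
        out_high = hi + rng.uniform(0.05, 0.4, size=n) * max(abs(hi), width)
        sick = np.where(side_high, out_high, out_low)
        return np.where(deficit, sick, healthy)
    if rtype == "categories":
        mapping = {float(k): float(v) for k, v in rule["mapping"].items()}
        zero_keys = [k for k, v in mapping.items() if v == 0]
        bad_keys = [k for k, v in mapping.items() if v > 0]
        healthy = rng.choice(zero_keys, size=n)
        sick = rng.choice(bad_keys, size=n)
        return np.where(deficit, sick, healthy)
    raise NotImplementedError(f"cannot invert rule type {rtype!r} for simulation")


def generate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate a full synthetic cohort table (deterministic given the seed)."""
    rng = rng or np.random.default_rng(config.seed)
    n = config.n

    df = pd.DataFrame(
        {
            "id": [f"S{i:07d}" for i in range(n)],
            "age": rng.uniform(20.0, 85.0, size=n),
            "sex": rng.choice(["male", "female"], size=n),
            "race": rng.choice(RACES, size=n, p=[0.45, 0.20, 0.25, 0.10]),
            "education": rng.choice(EDUCATION_LEVELS, size=n, p=[0.20, 0.25, 0.30, 0.25]),
            "marital": rng.choice(MARITAL_LEVELS, size=n, p=[0.55, 0.08, 0.15, 0.22]),
            "employment": rng.choice(["working", "non-working"], size=n, p=[0.60, 0.40]),
            "smoking": rng.choice(SMOKING_LEVELS, size=n, p=[0.55, 0.25, 0.20]),
            "cohort": rng.choice(["2007-2008", "2009-2010", "2011-2012"], size=n),
            "weight_2yr": rng.lognormal(10.3, 0.5, size=n),
        }
    )

    energy = rng.lognormal(config.energy_log_mean, config.energy_log_sd, size=n)
    new: dict[str, np.ndarray] = {
        "nut_energy_kcal": energy,
        "exam_weight_kg": np.clip(rng.normal(80.0, 15.0, size=n), 40.0, 160.0),
    }

    for col, slope in config.nutrient_energy_slopes.items():
        noise = rng.normal(0.0, config.nutrient_noise_cv * slope, size=n)
        new[col] = np.clip(slope * energy / 1000.0 + noise, 0.0, None)

    # alcohol: zero-inflated, not energy-coupled
    drinks = rng.random(n) < 0.40
    new["nut_alcohol_g"] = np.where(drinks, rng.lognormal(2.5, 0.8, size=n), 0.0)

    sex = df["sex"].to_numpy()
    age = df["age"].to_numpy()
    prevalences = dict(config.deficit_prevalences)

    # lab/exam items of the Nutrition Index fire at a flat prevalence
    ni = DeficitDefinitionSet.default_nutrition_index()
    for item in ni.items:
        if item.source == "nutrient":
            continue  # nutrient deficits emerge from the intake distributions
        p = prevalences.get(item.name, DEFAULT_LABEXAM_PREVALENCE)
        deficit = rng.random(n) < p
        new[item.column] = _sample_rule_value(rng, item, deficit, sex)

    # frailty items: prevalence rises with age on the logit scale
    fi = DeficitDefinitionSet.default_frailty_index()
    for item in fi.items:
        p0 = prevalences.get(item.name, DEFAULT_FRAILTY_PREVALENCE)
        if 0.0 < p0 < 1.0:
            logit = np.log(p0 / (1.0 - p0)) + config.age_logit_slope * (age - 50.0)
            p = 1.0 / (1.0 + np.exp(-logit))
        else:
            p = np.full(n, p0)
        deficit = rng.random(n) < p
        new[item.column] = _sample_rule_value(rng, item, deficit, sex)

    # BMI category follows the simulated BMI exam value
    new["bmi_category"] = pd.cut(
        new["exam_bmi"], bins=[-np.inf, 18.5, 25.0, 30.0, np.inf], labels=BMI_CATEGORIES, right=False
    ).astype(object)
    return pd.concat([df, pd.DataFrame(new, index=df.index)], axis=1)


def generate_followup(
    cohort: pd.DataFrame,
    frailty_scores,
    diet_scores,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival times under a log-linear hazard.

    hazard_i = baseline_hazard * exp(frailty_beta * FI_i / 0.1
                                     + diet_beta * score_i)

    Censoring is uniform on [followup_min_years, censor_years]; the event
    indicator is 1 iff the death time falls at or before the censor time.
    """
    if config.baseline_hazard <= 0:
        raise DomainError("baseline_hazard must be > 0")
    rng = rng or np.random.default_rng(config.seed)
    fi = np.asarray(frailty_scores, dtype=float)
    score = np.asarray(diet_scores, dtype=float)
    hazard = config.baseline_hazard * np.exp(config.frailty_beta * fi / 0.1 + config.diet_beta * score)
    death = rng.exponential(1.0 / hazard)
    censor = rng.uniform(config.followup_min_years, config.censor_years, size=len(fi))
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    return pd.DataFrame({"time_years": time, "event": event}, index=cohort.index)


def simulate_study(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Cohort + frailty index + designated diet score + follow-up, in one table.

    The designated ``driver_score`` enters the hazard divided by
    ``driver_unit_scale`` (0.1 by default, matching per-0.1-point hazard
    ratios for the deficit-accumulation scores).
    """
    rng = rng or np.random.default_rng(config.seed)
    df = generate_cohort(config, rng=rng)

    fi_defs = DeficitDefinitionSet.default_frailty_index()
    df["frailty_index"] = score_deficit_index(df, fi_defs)["value"]

    if config.driver_score == "nutrition_index":
        ni_defs = DeficitDefinitionSet.default_nutrition_index()
        df["nutrition_index"] = score_deficit_index(df, ni_defs)["value"]
        driver = df["nutrition_index"]
    elif config.driver_score == "frailty_index":
        driver = df["frailty_index"] * 0.0  # frailty already in the hazard
    else:
        from dietfrail.scoring import score_all

        df = score_all(df)
        driver = df[config.driver_score]

    fu = generate_followup(
        df,
        df["frailty_index"].to_numpy(),
        driver.to_numpy() / config.driver_unit_scale,
        config,
        rng=rng,
    )
    df["time_years"] = fu["time_years"]
    df["event"] = fu["event"]
    return df
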