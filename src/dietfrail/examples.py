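"""Reference example records: boundary diets and participants.

These constructions exercise the documented extremes of each score — the
fully deficient participant, the diet meeting every HEI-2015 best standard,
full Mediterranean-pattern adherence, and a diet meeting all nine DASH
goals. They are useful both as worked examples and as self-checks that an
edited configuration still attains its nominal score range.
"""

from __future__ import annotations

from dietfrail.deficits import DeficitDefinitionSet, all_deficit_record
from dietfrail.hei import HeiComponentStandard, default_standards
from dietfrail.patterns import (
    MDS_FAVORABLE,
    MDS_UNFAVORABLE,
    DashTarget,
    MdsMedianSet,
    default_dash_targets,
)

__all__ = [
    "fully_deficient_participant",
    "hei_perfect_diet",
    "mds_full_adherence_record",
    "dash_goal_diet",
]


def fully_deficient_participant(
    defs: DeficitDefinitionSet | None = None, sex: str = "female"
) -> dict:
    """A record triggering every deficit of ``defs`` (default: the 31-item
    Nutrition Index), hence scoring 1.0."""
    defs = defs or DeficitDefinitionSet.default_nutrition_index()
    return all_deficit_record(defs, sex=sex)


def hei_perfect_diet(
    standards: list[HeiComponentStandard] | None = None, energy: float = 2000.0
) -> dict:
    """A diet whose densities sit at every best HEI-2015 standard (total 100).

    Saturated fat is pinned at its best percent-energy standard and the
    unsaturated fats chosen so the (MUFA+PUFA)/SFA ratio reaches its
    maximum standard.
    """
    standards = standards or default_standards()
    rec: dict = {"nut_energy_kcal": energy}
    ratio_std = sat_std = None
    for s in standards:
        if s.basis == "ratio":
            ratio_std = s
            continue
        if s.name == "saturated_fats":
            sat_std = s
        if s.basis == "percent_energy":
            raw = s.standard_for_max / 100.0 * energy / s.kcal_per_g
        else:
            raw = s.standard_for_max * energy / 1000.0
        rec[s.column] = raw / s.scale
    if ratio_std is not None:
        sfa = rec.get("nut_saturated_fat_g")
        if sfa is None or sat_std is None:
            sfa = 10.0
            rec["nut_saturated_fat_g"] = sfa
        rec["nut_mufa_g"] = rec["nut_pufa_g"] = 0.5 * ratio_std.standard_for_max * sfa
    return rec


def mds_full_adherence_record(
    medians: MdsMedianSet, sex: str = "female", alcohol_g: float = 20.0
) -> dict:
    """A participant at the cohort median on every favourable component,
    strictly below it on every unfavourable one, with moderate alcohol
    (default 20 g/day, inside the female band), scoring the full 10."""
    rec: dict = {"sex": sex, "nut_alcohol_g": alcohol_g}
    for comp, col in MDS_FAVORABLE.items():
        m = medians.medians[comp]
        if col == "mufa_sfa_ratio":
            rec["nut_saturated_fat_g"] = 10.0
            rec["nut_mufa_g"] = 10.0 * max(m, 0.0)
        else:
            rec[col] = m
    for comp, col in MDS_UNFAVORABLE.items():
        rec[col] = 0.5 * medians.medians[comp]
    return rec


def dash_goal_diet(
    targets: list[DashTarget] | None = None, energy: float = 2000.0
) -> dict:
    """A diet whose nine basis-adjusted values each meet the DASH goal
    (scoring 9). 'At-least' targets sit exactly at the goal; 'at-most'
    targets sit 10% inside it."""
    targets = targets or default_dash_targets()
    rec: dict = {"nut_energy_kcal": energy}
    for t in targets:
        basis_value = t.goal if t.direction == "at-least" else 0.9 * t.goal
        if t.basis == "percent_energy":
            raw = basis_value / 100.0 * energy / t.kcal_per_g
        else:
            raw = basis_value * energy / 1000.0
        rec[t.column] = max(raw, 0.0)
    return rec
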