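# HEI-2015 scoring standards (USDA/NCI published cut-points).
# Adequacy components score max_points at/above standard_for_max and 0 at
# standard_for_min, linearly between; moderation components score max_points
# at/below standard_for_max and 0 at/above standard_for_min.
# basis: density_per_1000kcal (amount x 1000 / energy), percent_energy, ratio.
components:
  - name: total_fruits
    kind: adequacy
    max_points: 5
    basis: density_per_1000kcal
    column: fpe_total_fruits_cup
    standard_for_max: 0.8     # cup eq per 1000 kcal
    standard_for_min: 0.0
  - name: whole_fruits
    kind: adequacy
    max_points: 5
    basis: density_per_1000kcal
    column: fpe_whole_fruits_cup
    standard_for_max: 0.4
    standard_for_min: 0.0
  - name: total_vegetables
    kind: adequacy
    max_points: 5
    basis: density_per_1000kcal
    column: fpe_total_vegetables_cup
    standard_for_max: 1.1
    standard_for_min: 0.0
  - name: greens_and_beans
    kind: adequacy
    max_points: 5
    basis: density_per_1000kcal
    column: fpe_greens_beans_cup
    standard_for_max: 0.2
    standard_for_min: 0.0
  - name: whole_grains
    kind: adequacy
    max_points: 10
    basis: density_per_1000kcal
    column: fpe_whole_grains_oz
    standard_for_max: 1.5     # oz eq per 1000 kcal
    standard_for_min: 0.0
  - name: dairy
    kind: adequacy
    max_points: 10
    basis: density_per_1000kcal
    column: fpe_dairy_cup
    standard_for_max: 1.3
    standard_for_min: 0.0
  - name: total_protein_foods
    kind: adequacy
    max_points: 5
    basis: density_per_1000kcal
    column: fpe_total_protein_oz
    standard_for_max: 2.5
    standard_for_min: 0.0
  - name: seafood_and_plant_proteins
    kind: adequacy
    max_points: 5
    basis: density_per_1000kcal
    column: fpe_seafood_plant_protein_oz
    standard_for_max: 0.8
    standard_for_min: 0.0
  - name: fatty_acids
    kind: adequacy
    max_points: 10
    basis: ratio                # (MUFA + PUFA) / SFA
    standard_for_max: 2.5
    standard_for_min: 1.2
  - name: refined_grains
    kind: moderation
    max_points: 10
    basis: density_per_1000kcal
    column: fpe_refined_grains_oz
    standard_for_max: 1.8     # best: <= 1.8 oz eq per 1000 kcal
    standard_for_min: 4.3     # worst: >= 4.3 scores 0
  - name: sodium
    kind: moderation
    max_points: 10
    basis: density_per_1000kcal
    column: nut_sodium_mg
    scale: 0.001              # mg -> g, scored as g per 1000 kcal
    standard_for_max: 1.1
    standard_for_min: 2.0
  - name: added_sugars
    kind: moderation
    max_points: 10
    basis: percent_energy
    column: nut_added_sugar_g
    kcal_per_g: 4.0
    standard_for_max: 6.5     # best: <= 6.5 % of energy
    standard_for_min: 26.0
  - name: saturated_fats
    kind: moderation
    max_points: 10
    basis: percent_energy
    column: nut_saturated_fat_g
    kcal_per_g: 9.0
    standard_for_max: 8.0
    standard_for_min: 16.0
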