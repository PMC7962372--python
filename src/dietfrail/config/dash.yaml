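# Nine-item nutrient-based DASH adherence index.
# Meeting the goal scores 1 point; meeting the midpoint between the goal and
# the DASH-trial control-diet value scores 0.5; neither scores 0.
# basis: density_per_1000kcal or percent_energy; direction: at-least / at-most.
targets:
  - nutrient: protein
    column: nut_protein_g
    basis: percent_energy
    kcal_per_g: 4.0
    direction: at-least
    goal: 18.0          # % of energy
    control: 15.0
  - nutrient: fiber
    column: nut_fiber_g
    basis: density_per_1000kcal
    direction: at-least
    goal: 14.8          # g per 1000 kcal
    control: 4.2
  - nutrient: magnesium
    column: nut_magnesium_mg
    basis: density_per_1000kcal
    direction: at-least
    goal: 238.0         # mg per 1000 kcal
    control: 78.0
  - nutrient: calcium
    column: nut_calcium_mg
    basis: density_per_1000kcal
    direction: at-least
    goal: 590.0
    control: 214.0
  - nutrient: potassium
    column: nut_potassium_mg
    basis: density_per_1000kcal
    direction: at-least
    goal: 2238.0
    control: 830.0
  - nutrient: total_fat
    column: nut_total_fat_g
    basis: percent_energy
    kcal_per_g: 9.0
    direction: at-most
    goal: 27.0          # % of energy
    control: 37.0
  - nutrient: saturated_fat
    column: nut_saturated_fat_g
    basis: percent_energy
    kcal_per_g: 9.0
    direction: at-most
    goal: 6.0
    control: 16.0
  - nutrient: cholesterol
    column: nut_cholesterol_mg
    basis: density_per_1000kcal
    direction: at-most
    goal: 71.4          # mg per 1000 kcal
    control: 142.8
  - nutrient: sodium
    column: nut_sodium_mg
    basis: density_per_1000kcal
    direction: at-most
    goal: 1103.0        # mg per 1000 kcal
    control: 1999.0
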