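# Default 31-item Nutrition Index definition: 18 nutrient-intake items,
# 3 anthropometric items, and 10 nutrition-related blood tests.
# Cut-offs are editable defaults in conventional clinical/DRI-style units;
# direction "low" marks a deficit below the cut-off, "high" above it, and
# "band" marks values outside [low, high] (bounds inclusive-healthy).
name: nutrition_index
expected_count: 31
min_nonmissing_fraction: 0.8
items:
  # --- 18 nutrient-intake items -------------------------------------------
  - name: energy
    source: nutrient
    column: nut_energy_kcal
    rule: {type: threshold, direction: low, cutoff: 1500}   # kcal/day
  - name: energy_per_weight
    source: nutrient
    column: nut_energy_per_kg
    rule: {type: threshold, direction: low, cutoff: 25}     # kcal/kg/day
  - name: protein
    source: nutrient
    column: nut_protein_g
    rule: {type: threshold, direction: low, cutoff: 50}     # g/day
  - name: protein_per_weight
    source: nutrient
    column: nut_protein_per_kg
    rule: {type: threshold, direction: low, cutoff: 0.8}    # g/kg/day
  - name: carbohydrate
    source: nutrient
    column: nut_carbohydrate_g
    rule: {type: threshold, direction: low, cutoff: 130}    # g/day
  - name: pct_saturated_fat
    source: nutrient
    column: nut_sat_fat_pct_energy
    rule: {type: threshold, direction: high, cutoff: 10}    # % of energy
  - name: vitamin_a
    source: nutrient
    column: nut_vitamin_a_mcg
    rule: {type: threshold, direction: low, cutoff: 500}    # ug RAE/day
  - name: vitamin_c
    source: nutrient
    column: nut_vitamin_c_mg
    rule: {type: threshold, direction: low, cutoff: 60}     # mg/day
  - name: vitamin_b1
    source: nutrient
    column: nut_vitamin_b1_mg
    rule: {type: threshold, direction: low, cutoff: 1.0}    # mg/day
  - name: vitamin_b2
    source: nutrient
    column: nut_vitamin_b2_mg
    rule: {type: threshold, direction: low, cutoff: 1.1}    # mg/day
  - name: vitamin_b3
    source: nutrient
    column: nut_vitamin_b3_mg
    rule: {type: threshold, direction: low, cutoff: 14}     # mg NE/day
  - name: vitamin_b6
    source: nutrient
    column: nut_vitamin_b6_mg
    rule: {type: threshold, direction: low, cutoff: 1.2}    # mg/day
  - name: folate
    source: nutrient
    column: nut_folate_mcg
    rule: {type: threshold, direction: low, cutoff: 320}    # ug DFE/day
  - name: phosphorus
    source: nutrient
    column: nut_phosphorus_mg
    rule: {type: threshold, direction: low, cutoff: 580}    # mg/day
  - name: copper
    source: nutrient
    column: nut_copper_mg
    rule: {type: threshold, direction: low, cutoff: 0.7}    # mg/day
  - name: sodium
    source: nutrient
    column: nut_sodium_mg
    rule: {type: threshold, direction: high, cutoff: 2300}  # mg/day
  - name: selenium
    source: nutrient
    column: nut_selenium_mcg
    rule: {type: threshold, direction: low, cutoff: 45}     # ug/day
  - name: fish_oil
    source: nutrient
    column: nut_fish_oil_g
    rule: {type: threshold, direction: low, cutoff: 0.25}   # g EPA+DHA/day
  # --- 3 anthropometric items ---------------------------------------------
  - name: bmi
    source: exam
    column: exam_bmi
    rule: {type: band, low: 18.5, high: 30.0}               # kg/m^2
  - name: weight_change
    source: exam
    column: exam_weight_change_kg
    rule: {type: band, low: -4.5, high: 4.5}                # kg over past year
  - name: waist_circumference
    source: exam
    column: exam_waist_cm
    rule: {type: threshold, direction: high, cutoff: {male: 102, female: 88}}  # cm
  # --- 10 nutrition-related blood tests -----------------------------------
  - name: lymphocyte_count
    source: lab
    column: lab_lymphocyte_pct
    rule: {type: threshold, direction: low, cutoff: 20}     # % of WBC
  - name: hemoglobin
    source: lab
    column: lab_hemoglobin_g_dl
    rule: {type: threshold, direction: low, cutoff: {male: 13.0, female: 12.0}}  # g/dL
  - name: mean_corpuscular_volume
    source: lab
    column: lab_mcv_fl
    rule: {type: band, low: 80, high: 100}                  # fL
  - name: serum_albumin
    source: lab
    column: lab_albumin_g_dl
    rule: {type: threshold, direction: low, cutoff: 3.5}    # g/dL
  - name: vitamin_d
    source: lab
    column: lab_vitamin_d_nmol_l
    rule: {type: threshold, direction: low, cutoff: 50}     # nmol/L 25(OH)D
  - name: iron
    source: lab
    column: lab_iron_ug_dl
    rule: {type: threshold, direction: low, cutoff: 60}     # ug/dL
  - name: creatinine
    source: lab
    column: lab_creatinine_mg_dl
    rule: {type: threshold, direction: high, cutoff: 1.3}   # mg/dL
  - name: triglyceride
    source: lab
    column: lab_triglyceride_mg_dl
    rule: {type: threshold, direction: high, cutoff: 150}   # mg/dL
  - name: hdl_cholesterol
    source: lab
    column: lab_hdl_mg_dl
    rule: {type: threshold, direction: low, cutoff: {male: 40, female: 50}}  # mg/dL
  - name: glucose
    source: lab
    column: lab_glucose_mg_dl
    rule: {type: band, low: 70, high: 126}                  # mg/dL
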