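# Default 36-item deficit-accumulation frailty index: self-reported health
# conditions and functional limitations, vital signs, and laboratory tests.
# No item draws on dietary intake or nutritional status, so the index shares
# no source column with the Nutrition Index.
name: frailty_index
expected_count: 36
min_nonmissing_fraction: 0.8
items:
  # --- self-reported health (graded) --------------------------------------
  - name: general_health
    source: self_report
    column: sr_general_health            # 1 excellent ... 5 poor
    rule: {type: categories, mapping: {1: 0, 2: 0, 3: 0, 4: 0.5, 5: 1}}
  # --- self-reported diagnosed conditions (binary 0/1) ---------------------
  - name: arthritis
    source: self_report
    column: sr_arthritis
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: congestive_heart_failure
    source: self_report
    column: sr_congestive_heart_failure
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: coronary_heart_disease
    source: self_report
    column: sr_coronary_heart_disease
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: angina
    source: self_report
    column: sr_angina
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: heart_attack
    source: self_report
    column: sr_heart_attack
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: stroke
    source: self_report
    column: sr_stroke
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: emphysema
    source: self_report
    column: sr_emphysema
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: chronic_bronchitis
    source: self_report
    column: sr_chronic_bronchitis
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: liver_condition
    source: self_report
    column: sr_liver_condition
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: cancer
    source: self_report
    column: sr_cancer
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: diabetes
    source: self_report
    column: sr_diabetes
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: asthma
    source: self_report
    column: sr_asthma
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: thyroid_problem
    source: self_report
    column: sr_thyroid_problem
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: hypertension
    source: self_report
    column: sr_hypertension
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: kidney_condition
    source: self_report
    column: sr_kidney_condition
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: hearing_trouble
    source: self_report
    column: sr_hearing_trouble
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: vision_trouble
    source: self_report
    column: sr_vision_trouble
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: memory_problems
    source: self_report
    column: sr_memory_problems
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: depression
    source: self_report
    column: sr_depression
    rule: {type: threshold, direction: high, cutoff: 0.5}
  # --- self-reported functional limitations (binary 0/1) -------------------
  - name: difficulty_walking
    source: self_report
    column: sr_difficulty_walking
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: difficulty_stooping
    source: self_report
    column: sr_difficulty_stooping
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: difficulty_lifting
    source: self_report
    column: sr_difficulty_lifting
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: difficulty_dressing
    source: self_report
    column: sr_difficulty_dressing
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: difficulty_standing
    source: self_report
    column: sr_difficulty_standing
    rule: {type: threshold, direction: high, cutoff: 0.5}
  - name: limited_work
    source: self_report
    column: sr_limited_work
    rule: {type: threshold, direction: high, cutoff: 0.5}
  # --- vital signs ----------------------------------------------------------
  - name: systolic_bp
    source: exam
    column: exam_sbp_mmhg
    rule: {type: band, low: 90, high: 140}                  # mmHg
  - name: diastolic_bp
    source: exam
    column: exam_dbp_mmhg
    rule: {type: threshold, direction: high, cutoff: 90}    # mmHg
  - name: resting_pulse
    source: exam
    column: exam_pulse_bpm
    rule: {type: band, low: 50, high: 100}                  # beats/min
  # --- laboratory tests (none overlap the Nutrition Index panel) -----------
  - name: c_reactive_protein
    source: lab
    column: lab_crp_mg_dl
    rule: {type: threshold, direction: high, cutoff: 0.5}   # mg/dL
  - name: white_cell_count
    source: lab
    column: lab_wbc_10e3_ul
    rule: {type: band, low: 4.5, high: 11.0}                # 10^3/uL
  - name: platelet_count
    source: lab
    column: lab_platelet_10e3_ul
    rule: {type: band, low: 150, high: 400}                 # 10^3/uL
  - name: uric_acid
    source: lab
    column: lab_uric_acid_mg_dl
    rule: {type: threshold, direction: high, cutoff: 7.0}   # mg/dL
  - name: alkaline_phosphatase
    source: lab
    column: lab_alk_phos_u_l
    rule: {type: threshold, direction: high, cutoff: 120}   # U/L
  - name: blood_urea_nitrogen
    source: lab
    column: lab_bun_mg_dl
    rule: {type: threshold, direction: high, cutoff: 20}    # mg/dL
  - name: gamma_glutamyl_transferase
    source: lab
    column: lab_ggt_u_l
    rule: {type: threshold, direction: high, cutoff: 50}    # U/L
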