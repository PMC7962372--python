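parameter,unit,ref_mean,ref_sd,effect_score
protein,g,40.0,8.0,0.02
carbohydrate,g,140.0,25.0,0.10
total_fat,g,36.0,8.0,0.30
saturated_fat,g,14.0,4.0,0.37
mufa,g,13.0,3.5,-0.01
pufa,g,8.0,2.5,-0.34
omega3,g,0.80,0.40,-0.44
omega6,g,5.0,2.0,-0.16
cholesterol,mg,140.0,50.0,0.11
fiber,g,9.0,3.0,-0.66
vitamin_a,mcg,400.0,200.0,-0.40
vitamin_b1,mg,0.80,0.25,-0.10
vitamin_b2,mg,0.90,0.30,-0.07
vitamin_b3,mg,10.0,3.0,-0.25
vitamin_b6,mg,0.90,0.30,-0.36
vitamin_b12,mcg,2.4,1.2,0.11
vitamin_c,mg,45.0,25.0,-0.42
vitamin_d,mcg,3.0,2.0,-0.45
vitamin_e,mg,4.5,1.8,-0.42
folate,mcg,180.0,60.0,-0.19
beta_carotene,mcg,1800.0,1200.0,-0.58
iron,mg,7.0,2.0,0.03
magnesium,mg,150.0,40.0,-0.48
selenium,mcg,50.0,15.0,-0.19
zinc,mg,5.5,1.5,-0.31
caffeine,mg,80.0,60.0,-0.11
alcohol,g,6.0,8.0,-0.28
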