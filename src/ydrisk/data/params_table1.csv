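factor_id,level_id,is_reference,consensus_rr,us_prevalence,nhs_prevalence,applicability,nhs_unadjusted_rr,nhs_multivariate_rr
bmi,lt25,1,1.00,50.0,44.3,age<60,1.00,1.00
bmi,25_to_29,0,2.25,20.0,27.5,age<60,1.21,1.02
bmi,ge29,0,5.00,30.0,28.2,age<60,2.10,1.47
waist,le35in,1,1.00,54.7,85.1,age>=60,1.00,1.00
waist,gt35in,0,2.25,45.3,14.9,age>=60,1.47,1.23
smoking,current_ge25,0,5.00,5.0,1.9,always,2.12,2.73
smoking,current_15_24,0,2.25,10.0,4.6,always,2.48,3.15
smoking,current_le14,0,1.30,9.0,5.0,always,2.61,3.13
smoking,quit_lt2y,0,1.30,6.0,1.9,always,1.80,1.84
smoking,quit_2_10y,0,1.30,6.0,9.8,always,1.44,1.44
smoking,quit_10_20y,0,1.00,6.0,10.6,always,1.10,1.13
smoking,quit_ge20y,0,1.00,10.0,20.9,always,1.11,1.09
smoking,never,1,1.00,48.0,45.3,always,1.00,1.00
secondhand_smoke,rarely,1,1.00,90.0,67.4,not_current_smoker,1.00,1.00
secondhand_smoke,regularly,0,1.30,10.0,32.6,not_current_smoker,1.03,1.20
multivitamin,ge5_per_week,0,0.80,60.0,42.1,always,1.01,1.02
multivitamin,lt5_per_week,1,1.00,40.0,57.9,always,1.00,1.00
physical_activity,ge3h_per_week,0,0.55,19.0,21.3,always,0.79,0.85
physical_activity,lt3h_per_week,1,1.00,81.0,78.7,always,1.00,1.00
high_blood_pressure,yes,0,2.25,27.5,25.5,always,2.05,1.51
high_blood_pressure,no,1,1.00,72.5,74.5,always,1.00,1.00
diabetes,yes,0,2.25,8.1,3.9,always,4.41,3.20
diabetes,no,1,1.00,91.9,96.1,always,1.00,1.00
cholesterol,le159,1,1.00,14.0,7.1,always,1.00,1.00
cholesterol,160_199,0,1.30,35.0,25.2,always,0.83,0.86
cholesterol,200_239,0,2.25,30.0,47.8,always,1.15,0.98
cholesterol,240_299,0,5.00,15.0,17.1,always,1.48,1.26
cholesterol,ge300,0,7.00,6.0,2.8,always,2.56,2.00
family_history,yes,0,2.25,46.0,32.7,always,1.43,1.30
family_history,no,1,1.00,54.0,67.3,always,1.00,1.00
fish,ge2_per_week,0,0.55,35.0,25.0,always,0.91,0.90
fish,lt2_per_week,1,1.00,65.0,75.0,always,1.00,1.00
fruit_veg,ge5_per_day,0,0.55,26.0,57.3,always,1.08,1.11
fruit_veg,lt5_per_day,1,1.00,74.0,42.7,always,1.00,1.00
whole_grains,ge3_per_day,0,0.55,11.0,6.5,always,0.83,0.79
whole_grains,lt3_per_day,1,1.00,89.0,93.5,always,1.00,1.00
nuts,ge3_per_week,0,0.80,12.0,23.4,always,1.06,0.99
nuts,lt3_per_week,1,1.00,88.0,76.6,always,1.00,1.00
saturated_fat,ge2_per_day,0,1.30,71.0,25.2,always,1.18,1.08
saturated_fat,lt2_per_day,1,1.00,29.0,74.8,always,1.00,1.00
trans_fat,ge5_per_week,0,1.30,40.0,63.1,always,1.04,1.00
trans_fat,lt5_per_week,1,1.00,60.0,36.9,always,1.00,1.00
unsaturated_fat,ge5_per_week,0,0.80,15.0,38.7,always,0.91,0.94
unsaturated_fat,lt5_per_week,1,1.00,85.0,61.4,always,1.00,1.00
alcohol,ge1_per_day,0,0.55,11.0,15.7,always,0.82,0.79
alcohol,none,1,1.00,89.0,84.3,always,1.00,1.00
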