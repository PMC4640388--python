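subject_id,age,bmi,waist,smoking,secondhand_smoke,multivitamin,physical_activity,high_blood_pressure,diabetes,cholesterol,family_history,fish,fruit_veg,whole_grains,nuts,saturated_fat,trans_fat,unsaturated_fat,alcohol,chd_10yr,ffq_missing_items,kcal_per_day,prior_heart_disease
S000001,64,,le35in,never,rarely,lt5_per_week,ge3h_per_week,no,yes,200_239,no,lt2_per_week,lt5_per_day,lt3_per_day,lt3_per_week,lt2_per_day,ge5_per_week,lt5_per_week,none,0,5,1465,0
S000002,57,lt25,,quit_ge20y,rarely,lt5_per_week,lt3h_per_week,no,no,160_199,no,lt2_per_week,lt5_per_day,lt3_per_day,lt3_per_week,lt2_per_day,lt5_per_week,ge5_per_week,none,0,1,2747,0
S000003,51,25_to_29,,never,regularly,lt5_per_week,lt3h_per_week,yes,no,160_199,yes,ge2_per_week,lt5_per_day,lt3_per_day,ge3_per_week,lt2_per_day,lt5_per_week,lt5_per_week,ge1_per_day,0,0,2364,0
S000004,47,ge29,,quit_2_10y,rarely,lt5_per_week,lt3h_per_week,no,no,160_199,no,ge2_per_week,lt5_per_day,lt3_per_day,lt3_per_week,lt2_per_day,ge5_per_week,lt5_per_week,none,0,3,2671,0
S000005,60,,le35in,never,regularly,lt5_per_week,lt3h_per_week,yes,no,200_239,no,ge2_per_week,ge5_per_day,lt3_per_day,lt3_per_week,lt2_per_day,ge5_per_week,ge5_per_week,none,0,2,1651,0
S000006,73,,le35in,current_le14,,lt5_per_week,lt3h_per_week,no,yes,160_199,yes,ge2_per_week,ge5_per_day,lt3_per_day,lt3_per_week,lt2_per_day,lt5_per_week,lt5_per_week,none,0,2,2217,0
S000007,60,,le35in,never,rarely,ge5_per_week,lt3h_per_week,no,no,200_239,yes,lt2_per_week,lt5_per_day,lt3_per_day,lt3_per_week,lt2_per_day,lt5_per_week,lt5_per_week,none,0,0,2166,0
S000008,61,,le35in,quit_10_20y,regularly,ge5_per_week,lt3h_per_week,no,no,200_239,no,ge2_per_week,lt5_per_day,ge3_per_day,lt3_per_week,lt2_per_day,ge5_per_week,lt5_per_week,none,0,2,2404,0
S000009,63,,gt35in,quit_ge20y,rarely,lt5_per_week,ge3h_per_week,no,no,240_299,yes,lt2_per_week,ge5_per_day,lt3_per_day,lt3_per_week,lt2_per_day,lt5_per_week,lt5_per_week,none,0,3,1388,0
S000010,68,,le35in,quit_2_10y,regularly,lt5_per_week,lt3h_per_week,no,no,160_199,no,lt2_per_week,ge5_per_day,lt3_per_day,lt3_per_week,ge2_per_day,lt5_per_week,lt5_per_week,none,0,2,2024,0
S000011,58,lt25,,quit_lt2y,rarely,ge5_per_week,ge3h_per_week,yes,no,200_239,yes,lt2_per_week,ge5_per_day,lt3_per_day,lt3_per_week,lt2_per_day,ge5_per_week,ge5_per_week,none,0,4,2231,0
S000012,70,,le35in,never,rarely,ge5_per_week,lt3h_per_week,no,no,200_239,yes,lt2_per_week,lt5_per_day,lt3_per_day,lt3_per_week,lt2_per_day,ge5_per_week,ge5_per_week,none,0,4,2521,0
S000013,57,ge29,,never,rarely,ge5_per_week,lt3h_per_week,no,no,200_239,no,ge2_per_week,ge5_per_day,lt3_per_day,lt3_per_week,lt2_per_day,ge5_per_week,lt5_per_week,none,0,4,2249,0
S000014,64,,le35in,never,regularly,lt5_per_week,lt3h_per_week,yes,no,160_199,no,lt2_per_week,lt5_per_day,lt3_per_day,lt3_per_week,lt2_per_day,ge5_per_week,ge5_per_week,ge1_per_day,0,5,1917,0
S000015,73,,le35in,never,regularly,ge5_per_week,lt3h_per_week,no,no,200_239,yes,lt2_per_week,lt5_per_day,lt3_per_day,ge3_per_week,lt2_per_day,ge5_per_week,lt5_per_week,none,0,4,1936,0
S000016,74,,le35in,never,rarely,lt5_per_week,lt3h_per_week,no,no,160_199,no,ge2_per_week,ge5_per_day,lt3_per_day,ge3_per_week,lt2_per_day,lt5_per_week,ge5_per_week,ge1_per_day,0,1,1742,0
S000017,47,lt25,,quit_lt2y,regularly,lt5_per_week,lt3h_per_week,yes,no,160_199,no,lt2_per_week,ge5_per_day,lt3_per_day,lt3_per_week,lt2_per_day,ge5_per_week,lt5_per_week,none,0,5,1451,0
S000018,52,25_to_29,,never,rarely,ge5_per_week,lt3h_per_week,no,no,200_239,no,lt2_per_week,lt5_per_day,lt3_per_day,lt3_per_week,lt2_per_day,ge5_per_week,lt5_per_week,none,0,3,1644,0
S000019,69,,le35in,never,rarely,lt5_per_week,lt3h_per_week,yes,no,200_239,no,lt2_per_week,ge5_per_day,ge3_per_day,lt3_per_week,lt2_per_day,ge5_per_week,lt5_per_week,none,0,0,1433,0
S000020,55,ge29,,never,regularly,lt5_per_week,ge3h_per_week,no,no,160_199,yes,lt2_per_week,lt5_per_day,lt3_per_day,lt3_per_week,ge2_per_day,ge5_per_week,lt5_per_week,none,0,1,1562,0
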