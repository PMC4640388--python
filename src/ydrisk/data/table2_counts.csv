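stratum,category,n,cases,published_or,published_or_low,published_or_high,published_or_adj,published_or_adj_low,published_or_adj_high
overall,very_much_below_average,23140,290,0.42,0.32,0.55,0.43,0.33,0.56
overall,much_below_average,14941,308,0.70,0.53,0.91,0.68,0.52,0.89
overall,below_average,7278,173,0.81,0.61,1.07,0.78,0.59,1.04
overall,about_average,2321,68,1.00,,,1.00,,
overall,above_average,4369,166,1.31,0.98,1.74,1.32,0.99,1.76
overall,much_above_average,2836,115,1.40,1.03,1.90,1.55,1.14,2.11
overall,very_much_above_average,917,45,1.71,1.16,2.51,2.48,1.68,3.67
age_lt60,very_much_below_average,11390,56,0.39,0.22,0.71,0.40,0.22,0.71
age_lt60,much_below_average,6923,62,0.72,0.40,1.29,0.71,0.40,1.28
age_lt60,below_average,3271,38,0.94,0.51,1.73,0.93,0.50,1.72
age_lt60,about_average,1129,14,1.00,,,1.00,,
age_lt60,above_average,2156,47,1.78,0.97,3.24,1.73,0.95,3.15
age_lt60,much_above_average,1586,40,2.06,1.12,3.81,2.01,1.09,3.72
age_lt60,very_much_above_average,711,26,3.02,1.57,5.83,2.97,1.54,5.74
age_ge60,very_much_below_average,11750,234,0.43,0.32,0.58,0.43,0.32,0.59
age_ge60,much_below_average,8018,246,0.67,0.49,0.90,0.67,0.50,0.91
age_ge60,below_average,4007,135,0.74,0.53,1.01,0.74,0.54,1.02
age_ge60,about_average,1192,54,1.00,,,1.00,,
age_ge60,above_average,2213,119,1.20,0.86,1.67,1.20,0.87,1.67
age_ge60,much_above_average,1250,75,1.35,0.94,1.93,1.40,0.98,2.00
age_ge60,very_much_above_average,206,19,2.14,1.24,3.69,2.27,1.32,3.93
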