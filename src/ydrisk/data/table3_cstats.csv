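band,n,cases,published_c,published_c_low,published_c_high
overall,55802,1165,0.62,0.60,0.63
overall_age_adjusted,55802,1165,0.71,0.69,0.72
le55,14918,124,0.71,0.69,0.74
56_60,12469,160,0.66,0.65,0.68
61_65,11350,244,0.62,0.61,0.64
66_70,11222,386,0.62,0.61,0.64
gt70,5843,251,0.59,0.58,0.61
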