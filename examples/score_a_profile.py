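"""Score individual risk profiles with the YDR equation.

Builds three profiles against the packaged consensus parameter set and
prints each one's equation numerator (product of the subject's per-level
consensus RRs), denominator (product of population-average RRs over the
factors that apply to her), the resulting relative risk, and its category.
A relative risk of 1.0 means "average risk for your age and sex".
"""

import ydrisk

model = ydrisk.read_params()  # packaged consensus RRs, U.S. prevalences

# a 52-year-old at the reference level of every factor
reference_levels = {}
for f in model.factors:
    reference_levels[f.factor_id] = f.reference_level
best_case = ydrisk.RiskProfile("healthy_52", age=52, factor_levels=reference_levels)

# the same woman, but a heavy current smoker with high cholesterol and
# high blood pressure (her secondhand-smoke answer no longer applies)
risky_levels = dict(
    reference_levels,
    smoking="current_ge25",
    cholesterol="ge300",
    high_blood_pressure="yes",
)
worst_case = ydrisk.RiskProfile("smoker_52", age=52, factor_levels=risky_levels)

# age 65: adiposity is assessed as waist circumference, not BMI
older = ydrisk.RiskProfile(
    "active_65",
    age=65,
    factor_levels=dict(reference_levels, physical_activity="ge3h_per_week"),
)

for profile in (best_case, worst_case, older):
    result = ydrisk.score(profile, model)
    print(
        f"{profile.subject_id:>10s} (age {profile.age}): "
        f"numerator {result.numerator:6.2f}  denominator {result.denominator:5.2f}  "
        f"RR {result.relative_risk:5.2f}  -> {result.category}"
    )

print()
print(
    "The denominator anchors the average person at RR = 1: someone at every\n"
    "reference level scores well below 1 because the average person carries\n"
    "some risk-factor burden."
)
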