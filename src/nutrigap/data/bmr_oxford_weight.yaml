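# Oxford/Henry basal metabolic rate equations, weight-only form, adults.
# Transcribed from Henry CJK (2005), Public Health Nutr 8(7A):1133-1152,
# Table: BMR (MJ/day) = intercept + weight_coef * weight_kg.
# Bands are half-open [age_min, age_max); the last band closes at 80.
# Replace this file (or pass a height-aware table with height_coef, m) to
# swap equations without touching code.
- {sex: male,   age_min: 18, age_max: 30, weight_coef: 0.0669, intercept: 2.28}
- {sex: male,   age_min: 30, age_max: 60, weight_coef: 0.0592, intercept: 2.48}
- {sex: male,   age_min: 60, age_max: 80, weight_coef: 0.0563, intercept: 2.15}
- {sex: female, age_min: 18, age_max: 30, weight_coef: 0.0546, intercept: 2.33}
- {sex: female, age_min: 30, age_max: 60, weight_coef: 0.0407, intercept: 2.90}
- {sex: female, age_min: 60, age_max: 80, weight_coef: 0.0424, intercept: 2.38}
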