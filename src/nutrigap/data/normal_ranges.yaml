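# Normal ranges for the clinical panel. A value is "normal" (coded 1) iff
# it lies within [lower, upper], bounds inclusive, missing bound = open side;
# otherwise "abnormal" (coded 2).
# Sources: harmonised metabolic-syndrome criteria (Alberti et al. 2009,
# Circulation 120:1640) for WC, TG, HDL-C, blood pressure and fasting
# glucose; conventional clinical thresholds for BMI, total cholesterol,
# LDL-C, fasting insulin and HbA1c. Edit or replace to match local practice.
bmi:
  any: {upper: 25.0}          # kg/m^2, overweight at >= 25
wc:
  female: {upper: 80.0}       # cm
  male: {upper: 94.0}
tg:
  any: {upper: 150.0}         # mg/dL
total_chol:
  any: {upper: 200.0}         # mg/dL
hdl_c:
  female: {lower: 50.0}       # mg/dL
  male: {lower: 40.0}
ldl_c:
  any: {upper: 130.0}         # mg/dL
glucose:
  any: {upper: 100.0}         # mg/dL, impaired fasting glucose at >= 100
insulin:
  any: {upper: 25.0}          # uIU/mL
hba1c:
  any: {upper: 5.7}           # %, prediabetes at >= 5.7
sbp:
  any: {upper: 130.0}         # mmHg
dbp:
  any: {upper: 85.0}          # mmHg
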