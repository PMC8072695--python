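{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "nutrigap cohort CSV row",
 "description": "One subject per row; clinical columns may be empty (subject excluded before screening). Column order is nutrigap.cohort.CSV_COLUMNS.",
 "type": "object",
 "properties": {
  "id": {
   "type": "string"
  },
  "sex": {
   "type": "string",
   "enum": [
    "female",
    "male"
   ]
  },
  "age": {
   "type": "number",
   "description": "years"
  },
  "weight": {
   "type": "number",
   "description": "kg"
  },
  "height": {
   "type": "number",
   "description": "cm"
  },
  "centre": {
   "type": "string"
  },
  "energy": {
   "type": "number",
   "description": "MJ/day (or kcal/day if declared)",
   "minimum": 0
  },
  "carb": {
   "type": "number",
   "description": "%EI",
   "minimum": 0
  },
  "sugars": {
   "type": "number",
   "description": "%EI",
   "minimum": 0
  },
  "fat": {
   "type": "number",
   "description": "%EI",
   "minimum": 0
  },
  "sfa": {
   "type": "number",
   "description": "%EI",
   "minimum": 0
  },
  "ufa": {
   "type": "number",
   "description": "%EI",
   "minimum": 0
  },
  "pufa": {
   "type": "number",
   "description": "%EI",
   "minimum": 0
  },
  "protein": {
   "type": "number",
   "description": "g/day",
   "minimum": 0
  },
  "fibre": {
   "type": "number",
   "description": "g/day",
   "minimum": 0
  },
  "alcohol": {
   "type": "number",
   "description": "servings/day",
   "minimum": 0
  },
  "bmi": {
   "type": [
    "number",
    "null"
   ],
   "description": "kg/m^2"
  },
  "wc": {
   "type": [
    "number",
    "null"
   ],
   "description": "cm"
  },
  "tg": {
   "type": [
    "number",
    "null"
   ],
   "description": "mg/dL"
  },
  "total_chol": {
   "type": [
    "number",
    "null"
   ],
   "description": "mg/dL"
  },
  "hdl_c": {
   "type": [
    "number",
    "null"
   ],
   "description": "mg/dL"
  },
  "ldl_c": {
   "type": [
    "number",
    "null"
   ],
   "description": "mg/dL"
  },
  "glucose": {
   "type": [
    "number",
    "null"
   ],
   "description": "mg/dL"
  },
  "insulin": {
   "type": [
    "number",
    "null"
   ],
   "description": "uIU/mL"
  },
  "hba1c": {
   "type": [
    "number",
    "null"
   ],
   "description": "%"
  },
  "sbp": {
   "type": [
    "number",
    "null"
   ],
   "description": "mmHg"
  },
  "dbp": {
   "type": [
    "number",
    "null"
   ],
   "description": "mmHg"
  }
 },
 "required": [
  "id",
  "sex",
  "age",
  "weight",
  "height",
  "centre",
  "energy",
  "carb",
  "sugars",
  "fat",
  "sfa",
  "ufa",
  "pufa",
  "protein",
  "fibre",
  "alcohol"
 ]
}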