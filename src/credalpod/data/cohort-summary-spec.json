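{
  "description": "Exact marginal composition of the 116-patient chart-review cohort. Primary tumour site counts as printed sum to 115; one explicit NA record balances that column. Day-count columns carry the printed mean and range; the generator hits the mean exactly and places each printed extreme at least once.",
  "n": 116,
  "categorical": {
    "gender": {"male": 52, "female": 64},
    "age": {"20-40": 1, "41-65": 33, "66-80": 58, ">80": 24},
    "primary_tumour_site": {"gastrointestinal_tract": 40, "lung": 12, "breast": 15, "other": 48, "NA": 1},
    "place_of_death": {"home": 21, "hospital": 90, "nursing_home": 5},
    "area_of_residence": {"rural": 31, "urban": 85},
    "living_arrangements": {"alone": 40, "with_spouse": 65, "with_siblings": 2, "with_children": 6, "other": 3},
    "palliative_physician_visits": {"yes": 35, "no": 81},
    "palliative_nurse_visits": {"yes": 93, "no": 23},
    "social_worker": {"involved": 49, "not_involved": 67},
    "volunteers": {"involved": 71, "not_involved": 45},
    "general_practitioner": {"home_visits": 39, "no_home_visits": 54, "not_available": 23},
    "home_care_services": {"public": 33, "private": 41, "none": 42},
    "migrant_care_workers": {"provided": 3, "not_provided": 113},
    "kps": {"10-40": 41, "50-60": 63, "70-100": 12},
    "symptom_burden": {"none_low": 6, "medium": 36, "high": 74},
    "cancer_treatment": {"ongoing": 67, "discontinued": 49},
    "patient_awareness": {"open": 81, "closed": 34, "not_assessed": 1},
    "patient_preference": {"home": 34, "hospital": 9, "nursing_home": 1, "not_assessed": 72},
    "family_awareness": {"open": 87, "closed": 18, "not_assessed": 11},
    "family_conditions": {"suitable": 39, "unsuitable": 75, "not_assessed": 2},
    "family_preference": {"home": 29, "hospital": 20, "nursing_home": 1, "not_assessed": 66},
    "care_team_prediction": {"home": 39, "hospital": 75, "nursing_home": 2}
  },
  "integer": {
    "assessment_to_death_days": {"mean": 38, "min": 3, "max": 89},
    "diagnosis_to_death_days": {"mean": 922, "min": 2, "max": 10465},
    "chemo_to_death_days": {"mean": 34, "min": 0, "max": 247},
    "distance_km": {"mean": 4, "min": 1, "max": 74},
    "days_at_home_60": {"mean": 48, "min": 0, "max": 60},
    "days_in_hospital_60": {"mean": 10, "min": 0, "max": 60},
    "days_in_nursing_home_60": {"mean": 0, "min": 0, "max": 0},
    "hospitalisations_60": {"mean": 1, "min": 0, "max": 3}
  }
}
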