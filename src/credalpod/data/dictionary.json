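{
  "description": "Column dictionary for the 116-patient chart-review cohort. Single source of truth for column names and state vocabularies, shared by the synthetic-cohort generator and the reference credal network. Missing marker: the literal NA.",
  "columns": [
    {"name": "assessment_to_death_days", "type": "integer"},
    {"name": "gender", "type": "categorical", "states": ["male", "female"]},
    {"name": "age", "type": "categorical", "states": ["20-40", "41-65", "66-80", ">80"]},
    {"name": "primary_tumour_site", "type": "categorical", "states": ["gastrointestinal_tract", "lung", "breast", "other"], "allow_missing": true},
    {"name": "diagnosis_to_death_days", "type": "integer"},
    {"name": "place_of_death", "type": "categorical", "states": ["home", "hospital", "nursing_home"]},
    {"name": "chemo_to_death_days", "type": "integer"},
    {"name": "distance_km", "type": "integer"},
    {"name": "area_of_residence", "type": "categorical", "states": ["rural", "urban"]},
    {"name": "living_arrangements", "type": "categorical", "states": ["alone", "with_spouse", "with_siblings", "with_children", "other"]},
    {"name": "palliative_physician_visits", "type": "categorical", "states": ["yes", "no"]},
    {"name": "palliative_nurse_visits", "type": "categorical", "states": ["yes", "no"]},
    {"name": "social_worker", "type": "categorical", "states": ["involved", "not_involved"]},
    {"name": "volunteers", "type": "categorical", "states": ["involved", "not_involved"]},
    {"name": "general_practitioner", "type": "categorical", "states": ["home_visits", "no_home_visits", "not_available"]},
    {"name": "home_care_services", "type": "categorical", "states": ["public", "private", "none"]},
    {"name": "migrant_care_workers", "type": "categorical", "states": ["provided", "not_provided"]},
    {"name": "days_at_home_60", "type": "integer"},
    {"name": "days_in_hospital_60", "type": "integer"},
    {"name": "days_in_nursing_home_60", "type": "integer"},
    {"name": "hospitalisations_60", "type": "integer"},
    {"name": "kps", "type": "categorical", "states": ["10-40", "50-60", "70-100"]},
    {"name": "symptom_burden", "type": "categorical", "states": ["none_low", "medium", "high"]},
    {"name": "cancer_treatment", "type": "categorical", "states": ["ongoing", "discontinued"]},
    {"name": "patient_awareness", "type": "categorical", "states": ["open", "closed", "not_assessed"]},
    {"name": "patient_preference", "type": "categorical", "states": ["home", "hospital", "nursing_home", "not_assessed"]},
    {"name": "family_awareness", "type": "categorical", "states": ["open", "closed", "not_assessed"]},
    {"name": "family_conditions", "type": "categorical", "states": ["suitable", "unsuitable", "not_assessed"]},
    {"name": "family_preference", "type": "categorical", "states": ["home", "hospital", "nursing_home", "not_assessed"]},
    {"name": "care_team_prediction", "type": "categorical", "states": ["home", "hospital", "nursing_home"]}
  ]
}
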