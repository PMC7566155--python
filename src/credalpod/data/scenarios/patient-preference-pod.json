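{
  "name": "patient-preference-pod",
  "description": "The patient's own preference against the place of death; the study narrative reports a low influence (14%) compared with the family's preference.",
  "target": {"variable": "place_of_death", "state": "home"},
  "queries": [
    {"name": "patient prefers home", "evidence": {"patient_preference": "home"}},
    {"name": "patient preference not assessed", "evidence": {"patient_preference": "not_assessed"}}
  ],
  "impacts": [
    {"variable": "patient_preference", "mode": "do", "reference_impact_pct": 14,
     "note": "study narrative: impact of the patient's preference on POD, 14%"}
  ]
}
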