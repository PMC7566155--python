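{
  "name": "care-network-pod",
  "description": "Care-network and policy levers for patients and families with a congruent home preference; the study narrative reports that withdrawing specialist palliative home care decreases the home-death chance by 24%.",
  "target": {"variable": "place_of_death", "state": "home"},
  "evidence": {"family_preference": "home", "patient_preference": "home"},
  "queries": [
    {"name": "with specialist palliative home care", "do": {"palliative_home_care": "yes"}},
    {"name": "without specialist palliative home care", "do": {"palliative_home_care": "no"}}
  ],
  "impacts": [
    {"variable": "palliative_home_care", "mode": "do", "reference_impact_pct": 24,
     "note": "study narrative: without specialist palliative home care the chance of dying at home decreases by 24%"}
  ]
}
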