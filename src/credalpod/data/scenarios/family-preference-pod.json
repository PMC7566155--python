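{
  "name": "family-preference-pod",
  "description": "The family's preference for the last place of care against the place of death. The study narrative reports the highest overall impact on place of death (51%) for this variable and a high home-death probability (53-70%) when the family prefers home.",
  "target": {"variable": "place_of_death", "state": "home"},
  "queries": [
    {"name": "baseline"},
    {"name": "family prefers home", "evidence": {"family_preference": "home"}},
    {"name": "family prefers hospital", "evidence": {"family_preference": "hospital"}}
  ],
  "impacts": [
    {"variable": "family_preference", "mode": "do", "reference_impact_pct": 51,
     "note": "study narrative: family preference shows the highest overall impact on POD, 51%"}
  ]
}
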