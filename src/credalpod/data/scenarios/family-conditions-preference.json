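{
  "name": "family-conditions-preference",
  "description": "The family system's conditions for home care drive the family's preference for the last place of care.",
  "target": {"variable": "family_preference", "state": "home"},
  "queries": [
    {"name": "conditions suitable", "evidence": {"family_conditions": "suitable"}},
    {"name": "conditions unsuitable", "evidence": {"family_conditions": "unsuitable"}}
  ],
  "impacts": [
    {"variable": "family_conditions", "mode": "observe",
     "note": "spread of the family's home preference across the conditions states"},
    {"variable": "economic_resources", "mode": "observe", "reference_impact_pct": 20,
     "note": "study narrative: economic resources show an impact of 20% on the family's preference when no family carer is available (here computed without that stratification)"}
  ]
}
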