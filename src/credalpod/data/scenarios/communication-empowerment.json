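{
  "name": "communication-empowerment",
  "description": "Hypothetical intervention: open end-of-life communication plus good symptom control to make family conditions suitable for home care. The study narrative reports an increase of suitable-conditions probability by 35%, with a final influence on the place of death of 17%.",
  "target": {"variable": "family_conditions", "state": "suitable"},
  "queries": [
    {"name": "open communication, low burden", "do": {"eol_communication": "open", "symptom_burden": "none_low"}},
    {"name": "delayed communication, high burden", "do": {"eol_communication": "delayed", "symptom_burden": "high"}}
  ],
  "impacts": [
    {"variable": "eol_communication", "mode": "do", "reference_impact_pct": 35,
     "note": "study narrative: open communication and good symptom control enhance suitable conditions by 35% (communication manipulated alone here)"}
  ]
}
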