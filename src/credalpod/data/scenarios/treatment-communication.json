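{
  "name": "treatment-communication",
  "description": "Ongoing anticancer treatment prevents or delays open end-of-life communication; the study narrative puts the drop in open-communication probability near 40 percentage points between ongoing and discontinued treatment.",
  "target": {"variable": "eol_communication", "state": "open"},
  "queries": [
    {"name": "treatment ongoing", "evidence": {"cancer_treatment": "ongoing"}},
    {"name": "treatment discontinued", "evidence": {"cancer_treatment": "discontinued"}}
  ],
  "impacts": [
    {"variable": "cancer_treatment", "mode": "observe", "reference_impact_pct": 40,
     "note": "study narrative: ongoing treatment decreases open communication by 40%"}
  ]
}
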