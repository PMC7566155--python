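{
  "name": "default-7-term",
  "description": "Package default verbal probability scale: seven symmetric, deliberately overlapping terms. Editable; the elicitation study whose design this package follows did not publish its scale, so these values are declared, not reconstructed.",
  "terms": [
    {"term": "impossible", "lower": 0.0, "upper": 0.0},
    {"term": "very improbable", "lower": 0.0, "upper": 0.1},
    {"term": "improbable", "lower": 0.05, "upper": 0.35},
    {"term": "as probable as not", "lower": 0.45, "upper": 0.55},
    {"term": "probable", "lower": 0.65, "upper": 0.95},
    {"term": "very probable", "lower": 0.8, "upper": 1.0},
    {"term": "certain", "lower": 1.0, "upper": 1.0}
  ]
}
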