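{
  "description": "Myocarditis-type event: relative incidence 3.0, per-dose risk 1/100,000, whole population, throughput anchored to 50,000 doses/day in Ontario.",
  "design": {
    "relative_incidence": 3.0,
    "risk_days": 28,
    "observation_days": 180,
    "alpha": 0.05,
    "power": 0.90
  },
  "per_dose_risk": "1/100000",
  "stratum": "total",
  "throughput": {
    "mode": "anchored",
    "anchor_doses_per_day": 50000,
    "anchor_jurisdiction": "Ontario"
  },
  "national_aggregation": "summed",
  "rows": [
    ["Ontario"],
    ["Quebec"],
    ["British Columbia"],
    ["Alberta"],
    ["Manitoba"],
    ["Saskatchewan"],
    ["Nova Scotia"],
    ["New Brunswick"],
    ["Newfoundland and Labrador"],
    ["Prince Edward Island"],
    ["Ontario", "Quebec"],
    ["British Columbia", "Alberta", "Saskatchewan", "Manitoba", "Ontario", "Quebec"],
    ["Canada"]
  ]
}
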