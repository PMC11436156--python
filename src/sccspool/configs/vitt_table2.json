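{
  "description": "VITT-type event: relative incidence 5.0, per-dose risk 1.5/100,000, adults aged 18-39, flat throughput of 0.35% of the stratum population per day.",
  "design": {
    "relative_incidence": 5.0,
    "risk_days": 28,
    "observation_days": 180,
    "alpha": 0.05,
    "power": 0.90
  },
  "per_dose_risk": "1.5/100000",
  "stratum": "18-39",
  "throughput": {
    "mode": "flat",
    "daily_fraction": "0.0035"
  },
  "national_aggregation": "direct",
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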