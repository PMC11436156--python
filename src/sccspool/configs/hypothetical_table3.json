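{
  "description": "Hypothetical adverse-event rates for a relative-incidence-3.0 design over the whole population: an extremely rare event (1/1,000,000 per dose) and a more common one (1/10,000 per dose). The middle pooled row spans BC, AB, SK, MB and ON.",
  "design": {
    "relative_incidence": 3.0,
    "risk_days": 28,
    "observation_days": 180,
    "alpha": 0.05,
    "power": 0.90
  },
  "per_dose_risk": ["1/1000000", "1/10000"],
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
    {"label": "ON/PQ", "members": ["Ontario", "Quebec"]},
    {"label": "BC/AB/SK/MB/ON", "members": ["British Columbia", "Alberta", "Saskatchewan", "Manitoba", "Ontario"]},
    ["Canada"]
  ]
}
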