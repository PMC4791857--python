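{
 "replicates": 1000,
 "horizon": 100,
 "max_age": 20,
 "initial_years_since_flow": 1,
 "initial": {
  "HC": [
   61,
   62
  ],
  "M1F": [
   100,
   100
  ],
  "M2": [
   34,
   35
  ]
 },
 "subpops": [
  {
   "name": "HC",
   "K_static": 123,
   "flood_probability": 0.0,
   "adult_mortality": {
    "baseline": 0.2
   },
   "juvenile_mortality": {
    "baseline": 0.35
   },
   "ev_sd_fraction": 0.2,
   "fecundity_baseline": 1.06
  },
  {
   "name": "M1F",
   "K_max": 3800,
   "K_decay_range": [
    0.1,
    0.6
   ],
   "K_floor": 0,
   "K_quasi_zero": 18,
   "flood_probability": 0.05,
   "adult_mortality": {
    "baseline": 0.28,
    "flood": 0.4
   },
   "juvenile_mortality": {
    "baseline": 0.5,
    "flood": 1.0,
    "post_flood": 0.5,
    "window_years": 3,
    "annual_increment": 0.06,
    "cap": 0.95
   },
   "ev_sd_fraction": 0.2,
   "fecundity_baseline": 1.16,
   "fecundity_flood": 0.0,
   "fecundity_post_flood": 1.8
  },
  {
   "name": "M2",
   "K_static": 70,
   "flood_probability": 0.0,
   "adult_mortality": {
    "baseline": 0.22
   },
   "juvenile_mortality": {
    "baseline": 0.52
   },
   "ev_sd_fraction": 0.2,
   "fecundity_baseline": 1.56
  }
 ],
 "dispersal": {
  "distances_km": [
   {
    "from": "HC",
    "to": "M1F",
    "km": 182
   },
   {
    "from": "HC",
    "to": "M2",
    "km": 241
   },
   {
    "from": "M1F",
    "to": "M2",
    "km": 30
   }
  ],
  "adult_total": 0.05,
  "juvenile_total": 0.11,
  "flow_stratum": "M1F",
  "out_flood_multiplier": 5.419,
  "in_flood_multiplier": 0.102,
  "in_postflood_multiplier": 2.746
 }
}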