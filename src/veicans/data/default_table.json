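{
  "features": {
    "delta_le_1": 10,
    "delta_1_2": 6,
    "delta_2_3": 5,
    "delta_3_4": 3,
    "mod_low_voltage": 2,
    "grda": 2,
    "gpds": 2,
    "theta_4_5": 2,
    "theta_5_6": 1,
    "theta_6_8": 1,
    "alpha_ge_9": -1,
    "pdr": -1
  },
  "severe": [
    "burst_suppression",
    "ecs",
    "ncse",
    "unreactive"
  ],
  "max_score": "auto",
  "vocabulary_version": "table2-1hz-bins-v1",
  "provenance": "Published VE-ICANS grading system (theta 5-6 and 6-8 Hz bins share the merged +1 point value)"
}
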