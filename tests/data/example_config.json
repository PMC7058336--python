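{
  "true_c0": 0.002,
  "true_c1": 0.05,
  "levels": [
    0.0,
    0.0122,
    0.0243,
    0.0486,
    0.0972,
    0.243,
    0.81,
    2.43,
    4.21,
    12.2,
    24.3
  ],
  "replicates_per_level": 24,
  "accuracy_bias": 1.0,
  "interference_mix": {
    "normal": [
      1.0,
      1.0
    ]
  },
  "outlier_fraction": 0.0,
  "outlier_multiplier": 10.0,
  "seed": 20260919,
  "analyte": "synthetic",
  "experiment_id": "E1"
}
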