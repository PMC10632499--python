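{
  "name": "study2",
  "predictors": [
    {
      "name": "cognitive_restraint",
      "mean": 2.61,
      "sd": 0.56,
      "minimum": 1.0,
      "maximum": 4.0,
      "integer": false
    },
    {
      "name": "bmi",
      "mean": 27.99,
      "sd": 6.05,
      "minimum": 17.0,
      "maximum": 60.7,
      "integer": false
    }
  ],
  "predictor_correlation": 0.04,
  "outcome": {
    "name": "fv_intake",
    "intercept": 276.1,
    "coefficients": {
      "cognitive_restraint": 24.22,
      "bmi": -3.75,
      "cognitive_restraint:bmi": -2.84
    },
    "centers": {
      "cognitive_restraint": 2.61,
      "bmi": 27.99
    }
  },
  "noise_sd": 110.8926,
  "outcome_range": [
    29,
    709
  ],
  "seed": 0
}
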