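{
  "name": "study1",
  "predictors": [
    {
      "name": "health_literacy",
      "mean": 5.61,
      "sd": 1.54,
      "minimum": 0,
      "maximum": 9,
      "integer": true
    },
    {
      "name": "nutrition_knowledge",
      "mean": 10.73,
      "sd": 3.26,
      "minimum": 0,
      "maximum": 20,
      "integer": true
    }
  ],
  "predictor_correlation": 0.3,
  "outcome": {
    "name": "label_accuracy",
    "intercept": 1.53,
    "coefficients": {
      "nutrition_knowledge": 0.17,
      "health_literacy": 2.52,
      "health_literacy^2": -0.2
    },
    "centers": {}
  },
  "noise_sd": 2.3163,
  "outcome_range": [
    0,
    16
  ],
  "seed": 0
}
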