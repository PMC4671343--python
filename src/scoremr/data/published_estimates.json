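{
  "_comment": "Values printed in the original publication of the five-SNP homocysteine genetic-score MR analysis; used by reproduce-paper to flag agreement vs rounding-limited cells.",
  "score": {
    "hcy": {"beta": 0.09, "se": 0.004, "p": 2.7e-143},
    "t2d": {"beta": 0.008, "se": 0.008, "p": 0.34, "or": 1.01, "or_ci": [0.99, 1.024]},
    "glucose": {"beta": 0.0002, "se": 0.002, "p": 0.90},
    "ln_insulin": {"beta": -0.002, "se": 0.002, "p": 0.38}
  },
  "score_hcy_unrounded": {"beta": 0.092, "ci": [0.084, 0.100], "f": 650},
  "causal": {
    "t2d": {"or": 1.09, "ci": [0.92, 1.30], "p": 0.34},
    "glucose": {"beta": 0.002, "ci": [-0.037, 0.042], "p": 1.0},
    "ln_insulin": {"beta": -0.019, "ci": [-0.060, 0.023], "p": 0.335}
  },
  "observational_pivus": {
    "prevalent_t2d_or": 0.98,
    "incident_t2d_hr": 0.79,
    "glucose_beta": -0.001,
    "ln_insulin_beta": 0.056
  }
}
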